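import numpy as np
import pandas as pd
import pytest

from crossdomnet.preprocess import OtuTable
from crossdomnet.synthetic import make_precision, sample_counts


def make_table(counts, domain="16S", sample_ids=None, otu_ids=None, taxonomy=None):
    counts = np.asarray(counts)
    n, d = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    otu_ids = otu_ids or [f"otu{j}" for j in range(d)]
    return OtuTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        domain_label=domain,
        taxonomy=taxonomy or {},
    )


@pytest.fixture
def small_table():
    return make_table(
        [[10, 0, 3, 1], [5, 2, 0, 1], [8, 1, 7, 1]],
        taxonomy={"otu0": "k__Bacteria; p__Firmicutes",
                  "otu1": "k__Bacteria; p__Proteobacteria"},
    )


@pytest.fixture(scope="session")
def cluster_experiment():
    """A paired-domain synthetic experiment reused across tests."""
    truth = make_precision(20, 15, "cluster", n_cross_edges=8, seed=11)
    return sample_counts(truth, 150, seed=12)


def random_connected_graph(rng, n_max=8):
    """Small random connected graph for oracle suites."""
    import networkx as nx

    while True:
        n = int(rng.integers(3, n_max + 1))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.3, 0.8)), seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > 0:
            return g
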
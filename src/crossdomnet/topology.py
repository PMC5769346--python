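"""Network-topology battery for association networks.

Implements the comparison metrics used to contrast single-domain and
cross-domain microbial networks: component census, degree and shortest-path
statistics, normalized betweenness, categorical (phylum) assortativity,
deterministic modularity maximization with realized modularity, expected
commute time, spectral-scaling (Estrada) topological classification, attack
robustness curves, positive-edge percentage, keystone candidate tables,
status-exclusive subnetworks, per-module enrichment, and Welch-test network
comparison.

All topological metrics operate on the unweighted, sign-agnostic graph (an
edge is present or absent); the signed partial-correlation weights enter only
the positive-edge percentage and the keystone/strength reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .inference import AssociationNetwork

__all__ = [
    "ComponentCensus",
    "ModulePartition",
    "EstradaClassification",
    "RobustnessCurve",
    "TopologyReport",
    "component_census",
    "degree_stats",
    "betweenness",
    "path_length_stats",
    "modularity_partition",
    "assortativity_by_attribute",
    "expected_commute_time",
    "attack_robustness",
    "positive_edge_percentage",
    "estrada_classify",
    "keystone_scatter",
    "status_exclusive_subnetworks",
    "module_enrichment",
    "compare_networks",
    "topology_report",
]


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, AssociationNetwork) else net


# ---------------------------------------------------------------------------
# components / degrees / paths / betweenness


@dataclass
class ComponentCensus:
    sizes: list[int]                # sorted descending
    n_nodes: int

    @property
    def lcc_size(self) -> int:
        return self.sizes[0] if self.sizes else 0

    @property
    def lcc_fraction(self) -> float:
        return self.lcc_size / self.n_nodes if self.n_nodes else 0.0

    @property
    def n_singletons(self) -> int:
        return sum(1 for s in self.sizes if s == 1)

    @property
    def n_dyads(self) -> int:
        return sum(1 for s in self.sizes if s == 2)

    def fractions(self) -> list[float]:
        return [s / self.n_nodes for s in self.sizes]


def component_census(net) -> ComponentCensus:
    g = _as_graph(net)
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return ComponentCensus(sizes=sizes, n_nodes=g.number_of_nodes())


def degree_stats(net) -> tuple[float, float]:
    """Mean and (population) SD of unweighted node degree, singletons included."""
    g = _as_graph(net)
    deg = np.array([d for _, d in g.degree()], float)
    if deg.size == 0:
        return 0.0, 0.0
    return float(deg.mean()), float(deg.std())


def betweenness(net, normalized: bool = True) -> dict[str, float]:
    """Unweighted shortest-path betweenness centrality per node.

    Normalization divides by (n-1)(n-2)/2, the number of ordered pairs a node
    could mediate in an undirected graph.
    """
    g = _as_graph(net)
    return nx.betweenness_centrality(g, normalized=normalized, weight=None)


@dataclass
class PathLengthStats:
    mean: float
    sd: float
    n_connected_pairs: int
    n_disconnected_pairs: int


def path_length_stats(net, node_subset=None, domain: str | None = None) -> PathLengthStats:
    """Mean/SD of pairwise shortest-path lengths within a node subset.

    Disconnected pairs are excluded from the average and counted separately;
    the subset may be given explicitly or as a ``domain`` filter on the node
    attribute (paths may still run through nodes outside the subset).
    """
    g = _as_graph(net)
    if domain is not None:
        node_subset = [n for n, d in g.nodes(data="domain") if d == domain]
    nodes = list(node_subset) if node_subset is not None else list(g.nodes)
    node_set = set(nodes)
    lengths = []
    seen_connected = set()
    for src in nodes:
        dist = nx.single_source_shortest_path_length(g, src)
        for tgt, L in dist.items():
            if tgt in node_set and tgt != src:
                key = (src, tgt) if src <= tgt else (tgt, src)
                if key not in seen_connected:
                    seen_connected.add(key)
                    lengths.append(L)
    n_total_pairs = len(nodes) * (len(nodes) - 1) // 2
    n_conn = len(lengths)
    if n_conn == 0:
        raise ValueError("no connected pairs in the requested node subset")
    arr = np.array(lengths, float)
    return PathLengthStats(
        mean=float(arr.mean()),
        sd=float(arr.std()),
        n_connected_pairs=n_conn,
        n_disconnected_pairs=n_total_pairs - n_conn,
    )


# ---------------------------------------------------------------------------
# modularity


@dataclass
class ModulePartition:
    """Modularity-maximizing partition of (by default) the largest component."""

    assignment: dict[str, int]
    n_modules: int
    modularity: float
    realized_modularity: float
    analyzed_nodes: list[str] = field(default_factory=list)

    def members(self, module_id: int) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module_id]


def _modularity_matrix(g: nx.Graph, nodes: list[str]) -> tuple[np.ndarray, np.ndarray, float]:
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    k = a.sum(axis=1)
    two_m = k.sum()
    b = a - np.outer(k, k) / two_m
    return b, k, two_m


def _kl_refine(b_g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan–Lin style fine-tuning of a two-way split.

    Repeatedly passes over all vertices, moving each (once per pass, in order
    of best gain) and keeping the best intermediate state; stops when a full
    pass yields no improvement. Deterministic: ties break toward the lowest
    vertex index.
    """
    s = s.copy()
    n = s.size
    best_q = float(s @ b_g @ s)
    improved = True
    while improved:
        improved = False
        moved = np.zeros(n, dtype=bool)
        s_work = s.copy()
        q_work = best_q
        states = []
        for _ in range(n):
            gains = np.full(n, -np.inf)
            for v in range(n):
                if not moved[v]:
                    # delta of s^T B s when flipping v
                    gains[v] = -4.0 * s_work[v] * (b_g[v] @ s_work) + 4.0 * b_g[v, v]
            v = int(np.argmax(gains))
            s_work[v] = -s_work[v]
            moved[v] = True
            q_work = q_work + gains[v]
            states.append((q_work, s_work.copy()))
        q_candidates = [q for q, _ in states]
        k = int(np.argmax(q_candidates))
        if q_candidates[k] > best_q + 1e-12:
            best_q = q_candidates[k]
            s = states[k][1]
            improved = True
    return s


def _spectral_split(b_g: np.ndarray) -> np.ndarray | None:
    """Leading-eigenvector bisection of a (generalized) modularity matrix."""
    evals, evecs = np.linalg.eigh(b_g)
    lead = evecs[:, -1]
    if evals[-1] <= 1e-12:
        return None
    s = np.where(lead >= 0, 1.0, -1.0)
    if np.all(s == s[0]):
        return None
    s = _kl_refine(b_g, s)
    if np.all(s == s[0]):
        return None
    return s


def modularity_partition(net, seed: int | None = None, on_lcc: bool = True) -> ModulePartition:
    """Deterministic modularity maximization (spectral bisection + refinement).

    Newman's leading-eigenvector method: recursively bisect using the sign
    pattern of the top eigenvector of the (generalized) modularity matrix,
    fine-tune each split with Kernighan–Lin vertex moves, and stop a branch
    when no split increases modularity. The algorithm is deterministic; the
    ``seed`` argument is accepted for interface uniformity but unused. The
    number of modules emerges from the recursion. Realized modularity is the
    fraction of edges that fall within modules.
    """
    g = _as_graph(net)
    if on_lcc:
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        if not comps:
            raise ValueError("empty graph")
        nodes = sorted(comps[0])
        g = g.subgraph(nodes)
    else:
        nodes = sorted(g.nodes)
    if g.number_of_edges() == 0:
        raise ValueError("modularity is undefined on an edgeless graph")

    b, k, two_m = _modularity_matrix(g, nodes)
    idx_all = np.arange(len(nodes))
    groups: list[np.ndarray] = []

    def recurse(idx: np.ndarray) -> None:
        if idx.size <= 1:
            groups.append(idx)
            return
        b_sub = b[np.ix_(idx, idx)]
        b_g = b_sub - np.diag(b_sub.sum(axis=1))  # generalized modularity matrix
        s = _spectral_split(b_g)
        if s is None or float(s @ b_g @ s) <= 1e-12:
            groups.append(idx)
            return
        recurse(idx[s > 0])
        recurse(idx[s < 0])

    recurse(idx_all)
    assignment = {}
    for mod_id, idx in enumerate(groups):
        for i in idx:
            assignment[nodes[i]] = mod_id

    communities = [set(nodes[i] for i in idx) for idx in groups]
    q = nx.community.modularity(g, communities, weight=None)
    within = sum(
        1 for u, v in g.edges if assignment[u] == assignment[v]
    )
    realized = within / g.number_of_edges()
    return ModulePartition(
        assignment=assignment,
        n_modules=len(groups),
        modularity=float(q),
        realized_modularity=float(realized),
        analyzed_nodes=list(nodes),
    )


def assortativity_by_attribute(net, attribute: str = "phylum") -> float:
    """Nominal assortativity coefficient for a categorical node attribute.

    Unlabeled nodes count as their own ``"unclassified"`` category. Returns
    NaN (with a warning) when every node carries a single category, where the
    coefficient is undefined (0/0).
    """
    g = _as_graph(net).copy()
    for n, d in g.nodes(data=True):
        if not d.get(attribute):
            g.nodes[n][attribute] = "unclassified"
    values = {d[attribute] for _, d in g.nodes(data=True)}
    if len(values) < 2:
        warnings.warn(
            f"assortativity undefined: single {attribute!r} category",
            UserWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(nx.attribute_assortativity_coefficient(g, attribute))


# ---------------------------------------------------------------------------
# expected commute time


def expected_commute_time(
    net, normalization: str = "mean", restrict_to_lcc: bool = False
) -> float:
    """Expected commute time of the random walk on the graph.

    The commute time between nodes i and j is the expected number of hops for
    a random walk to go from i to j and return; it equals ``2m * R_eff(i,j)``
    with m the edge count and R_eff the effective resistance. Summing over
    pairs via the Laplacian spectrum: ``sum_{i<j} R_eff = n * sum(1/mu)`` over
    the nonzero Laplacian eigenvalues mu. ``normalization='mean'`` averages
    over unordered pairs; ``'sum'`` returns the total.
    """
    g = _as_graph(net)
    if not nx.is_connected(g):
        if not restrict_to_lcc:
            raise ValueError(
                "commute time requires a connected graph; pass "
                "restrict_to_lcc=True to analyze the largest component"
            )
        warnings.warn(
            "graph disconnected; computing commute time on the largest component",
            UserWarning,
            stacklevel=2,
        )
        lcc = max(nx.connected_components(g), key=len)
        g = g.subgraph(lcc)
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n < 2:
        return 0.0
    lap = nx.laplacian_matrix(g, weight=None).toarray().astype(float)
    mu = np.linalg.eigvalsh(lap)[1:]  # drop the single zero eigenvalue
    total_resistance = n * float(np.sum(1.0 / mu))
    total_commute = 2.0 * m * total_resistance
    if normalization == "sum":
        return total_commute
    if normalization == "mean":
        return total_commute / (n * (n - 1) / 2.0)
    raise ValueError("normalization must be 'mean' or 'sum'")


# ---------------------------------------------------------------------------
# attack robustness


@dataclass
class RobustnessCurve:
    strategy: str
    fraction_removed: np.ndarray
    fraction_in_lcc: np.ndarray      # relative to the starting LCC size
    area_under_curve: float
    recompute: bool = True
    n_random_repeats: int = 1
    seed: int | None = None


def _attack_once(
    g: nx.Graph, strategy: str, recompute: bool, rng: np.random.Generator | None
) -> np.ndarray:
    """LCC-fraction trajectory for one removal ordering."""
    g = g.copy()
    n0 = g.number_of_nodes()
    lcc0 = max((len(c) for c in nx.connected_components(g)), default=0)
    fractions = [1.0]

    def criterion(h: nx.Graph) -> dict:
        if strategy == "degree":
            return dict(h.degree())
        return nx.betweenness_centrality(h, normalized=True, weight=None)

    if strategy == "random":
        order = list(g.nodes)
        order = [order[i] for i in rng.permutation(len(order))]
    elif not recompute:
        scores = criterion(g)
        order = sorted(g.nodes, key=lambda v: (-scores[v], str(v)))
    else:
        order = None

    for step in range(n0):
        if order is not None:
            victim = order[step]
        else:
            scores = criterion(g)
            victim = min(g.nodes, key=lambda v: (-scores[v], str(v)))
        g.remove_node(victim)
        lcc = max((len(c) for c in nx.connected_components(g)), default=0)
        fractions.append(lcc / lcc0 if lcc0 else 0.0)
    return np.array(fractions)


def attack_robustness(
    net,
    strategy: str = "betweenness",
    recompute: bool = True,
    seed: int | None = None,
    n_random_repeats: int = 100,
) -> RobustnessCurve:
    """Sequential node removal and the decay of the largest component.

    Nodes are removed one at a time in decreasing order of the chosen
    criterion (recomputed after every removal when ``recompute`` is set, the
    adaptive attack) or uniformly at random (averaged over
    ``n_random_repeats`` seeded orderings). The curve tracks the largest
    connected component relative to its starting size; a larger area under
    the curve means a more robust network.
    """
    if strategy not in ("betweenness", "degree", "random"):
        raise ValueError("strategy must be 'betweenness', 'degree' or 'random'")
    g = _as_graph(net)
    n0 = g.number_of_nodes()
    if n0 == 0:
        raise ValueError("empty graph")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        curves = [
            _attack_once(g, strategy, recompute, rng) for _ in range(n_random_repeats)
        ]
        fractions = np.mean(curves, axis=0)
        repeats = n_random_repeats
    else:
        fractions = _attack_once(g, strategy, recompute, None)
        repeats = 1
    removed = np.arange(n0 + 1) / n0
    auc = float(np.trapezoid(fractions, removed))
    return RobustnessCurve(
        strategy=strategy,
        fraction_removed=removed,
        fraction_in_lcc=fractions,
        area_under_curve=auc,
        recompute=recompute,
        n_random_repeats=repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# signed-weight summaries


def positive_edge_percentage(net) -> float:
    """Fraction of edges with positive partial correlation (PEP).

    Undefined (NaN, with a warning) on an edgeless graph.
    """
    g = _as_graph(net)
    weights = [d.get("partial_correlation", d.get("weight", 0.0)) for _, _, d in g.edges(data=True)]
    if not weights:
        warnings.warn("PEP undefined on an edgeless graph", UserWarning, stacklevel=2)
        return float("nan")
    return float(np.mean([w > 0 for w in weights]))


# ---------------------------------------------------------------------------
# Estrada spectral-scaling classification


@dataclass
class EstradaClassification:
    """Topological class from deviations of odd subgraph centrality.

    For networks with good expansion, ``SC_odd(i) = sinh(l1) * v1_i**2`` with
    l1 the principal adjacency eigenvalue and v1 its eigenvector (the
    spectral scaling law). Modular structure adds further large *positive*
    adjacency eigenvalues (one per community), pushing ``SC_odd`` above the
    law; bipartite-like branches (a periphery of trees) add large *negative*
    eigenvalues, pulling it below. The log10-scale departures therefore
    classify the topology: homogeneous (all nodes on one scaling line) ->
    class I (good expansion); positive departures only -> class II (modular);
    negative only -> class III (core-periphery); both -> class IV (mixed).
    """

    estrada_class: str
    deviations: dict[str, float]
    slope: float
    intercept: float
    tolerance: float

    @property
    def max_positive(self) -> float:
        return max(self.deviations.values(), default=0.0)

    @property
    def max_negative(self) -> float:
        return min(self.deviations.values(), default=0.0)


def estrada_classify(net, tolerance: float = 0.01) -> EstradaClassification:
    """Classify network topology by spectral scaling of subgraph centrality.

    Computed on the largest connected component. The odd-walk subgraph
    centrality ``SC_odd(i) = sum_j v_ji^2 sinh(l_j)`` is compared against the
    principal-eigenpair prediction ``sinh(l1) v1_i^2``; deviations are
    ``log10 SC_odd(i) - log10 prediction``. When the deviation *spread*
    (max - min) is within ``tolerance``, all nodes share one scaling line —
    slope-2 log-log scaling holds and the network is class I (a uniform
    offset is the finite-size correction from subdominant eigenvalues, not
    topological heterogeneity; vertex-transitive graphs land here exactly).
    Otherwise the sign pattern of deviations beyond ``tolerance`` decides:
    positive only -> II (modular), negative only -> III (core-periphery),
    both -> IV. A least-squares
    fit of ``log10 SC_odd`` on ``log10 v1`` is reported alongside (slope 2,
    intercept log10 sinh(l1) under perfect scaling).
    """
    g = _as_graph(net)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if not comps:
        raise ValueError("empty graph")
    nodes = sorted(comps[0])
    if len(nodes) < 2:
        raise ValueError("Estrada classification needs at least a connected pair")
    a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes, weight=None)
    evals, evecs = np.linalg.eigh(a)
    l1 = evals[-1]
    v1 = evecs[:, -1]
    if v1.sum() < 0:
        v1 = -v1  # Perron vector is positive on a connected graph
    v1 = np.abs(v1)
    # odd-walk subgraph centrality, rescaled by exp(-l1) for numerical range:
    # sinh(l_j) * exp(-l1) = (exp(l_j - l1) - exp(-l_j - l1)) / 2

    sinh_scaled = 0.5 * (np.exp(evals - l1) - np.exp(-evals - l1))
    sc_odd = (evecs**2 * sinh_scaled).sum(axis=1)      # = SC_odd * exp(-l1)
    pred = 0.5 * (1.0 - np.exp(-2.0 * l1)) * v1**2     # = sinh(l1) v1^2 * exp(-l1)
    if (sc_odd <= 0).any():
        raise ValueError(
            "odd subgraph centrality non-positive (bipartite-like spectrum); "
            "spectral scaling classification undefined"
        )
    dev = np.log10(sc_odd) - np.log10(pred)
    if dev.max() - dev.min() <= tolerance:
        cls = "I"
    else:
        has_pos = bool((dev > tolerance).any())
        has_neg = bool((dev < -tolerance).any())
        cls = {
            (False, False): "I",
            (True, False): "II",   # modular: extra positive eigenvalues
            (False, True): "III",  # core-periphery: dominant negative eigenvalues
            (True, True): "IV",
        }[(has_pos, has_neg)]
    log_v1 = np.log10(v1)
    if np.ptp(log_v1) < 1e-12:  # vertex-transitive: fit degenerate, law exact
        slope, intercept = 2.0, float(np.log10(sc_odd).mean() - 2.0 * log_v1.mean())
    else:
        slope, intercept = np.polyfit(log_v1, np.log10(sc_odd), 1)
    return EstradaClassification(
        estrada_class=cls,
        deviations=dict(zip(nodes, map(float, dev))),
        slope=float(slope),
        intercept=float(intercept),
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# keystone candidates, exclusivity, enrichment


def keystone_scatter(net, counts=None) -> pd.DataFrame:
    """Per-node degree vs normalized betweenness, with maxima flagged.

    Nodes maximal in degree and/or betweenness are candidate keystone taxa
    (ties all flagged). When an :class:`~crossdomnet.preprocess.OtuTable` (or
    mapping of domain label to table) is supplied, each node also gets its
    maximum per-sample relative abundance and its prevalence (fraction of
    samples with nonzero counts), computed from the raw counts.
    """
    g = _as_graph(net)
    btw = nx.betweenness_centrality(g, normalized=True, weight=None)
    rows = []
    for n, d in g.nodes(data=True):
        rows.append(
            {
                "node": n,
                "degree": g.degree(n),
                "betweenness": btw[n],
                "domain": d.get("domain", ""),
                "phylum": d.get("phylum", ""),
            }
        )
    df = pd.DataFrame(rows).set_index("node")
    if len(df):
        df["is_max_degree"] = df["degree"] == df["degree"].max()
        df["is_max_betweenness"] = np.isclose(df["betweenness"], df["betweenness"].max())

    if counts is not None:
        tables = counts if isinstance(counts, dict) else {getattr(counts, "domain_label", ""): counts}
        max_ra = {}
        prev = {}
        for dom, table in tables.items():
            arr = table.counts.to_numpy(float)
            totals = arr.sum(axis=1, keepdims=True)
            totals[totals == 0] = 1.0
            ra = arr / totals
            for j, otu in enumerate(table.otu_ids):
                for key in (f"{dom}:{otu}", otu):
                    max_ra[key] = float(ra[:, j].max())
                    prev[key] = float((arr[:, j] > 0).mean())
        df["max_relative_abundance"] = [max_ra.get(n, np.nan) for n in df.index]
        df["prevalence"] = [prev.get(n, np.nan) for n in df.index]
    return df.sort_values(["degree", "betweenness"], ascending=False)


@dataclass
class ExclusiveSubnetwork:
    exclusive_nodes: list[str]
    subnetwork: nx.Graph           # exclusive OTUs plus their graph neighbors
    census: ComponentCensus | None


def status_exclusive_subnetworks(
    net, counts, sample_labels: dict[str, str], group: str
) -> ExclusiveSubnetwork:
    """Subnetwork of OTUs found only in one sample group, plus neighbors.

    An OTU is group-exclusive iff its raw (pre-pseudocount) counts are
    nonzero only in samples carrying ``group`` in ``sample_labels`` and it is
    present in at least one sample. The subnetwork is the closed neighborhood
    (exclusive OTUs and their direct neighbors) induced in the graph; absent
    exclusive OTUs yield an empty result, not an error.
    """
    g = _as_graph(net)
    tables = counts if isinstance(counts, dict) else {getattr(counts, "domain_label", ""): counts}
    exclusive: list[str] = []
    for dom, table in tables.items():
        labels = np.array([sample_labels.get(str(s)) for s in table.sample_ids], dtype=object)
        in_group = labels == group
        arr = table.counts.to_numpy()
        present_in = arr > 0
        for j, otu in enumerate(table.otu_ids):
            col = present_in[:, j]
            if col.any() and not col[~in_group].any():
                for key in (f"{dom}:{otu}", otu):
                    if key in g:
                        exclusive.append(key)
                        break
    exclusive = sorted(set(exclusive))
    members = set(exclusive)
    for n in exclusive:
        members.update(g.neighbors(n))
    sub = g.subgraph(sorted(members)).copy()
    census = component_census(sub) if members else None
    return ExclusiveSubnetwork(
        exclusive_nodes=exclusive, subnetwork=sub, census=census
    )


def module_enrichment(
    partition: ModulePartition, flagged: set[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric enrichment of a flagged node set per module.

    For each module, the p-value is the hypergeometric upper tail of drawing
    at least the observed number of flagged nodes in a module-sized draw from
    the partitioned node population; Benjamini-Hochberg adjusted across
    modules.
    """
    nodes = list(partition.assignment)
    unknown = set(flagged) - set(nodes)
    if unknown:
        raise ValueError(f"flagged nodes not in partition: {sorted(unknown)[:5]}")
    n_total = len(nodes)
    n_flagged = len(set(flagged))
    rows = []
    for mod in range(partition.n_modules):
        members = partition.members(mod)
        k = len(set(members) & set(flagged))
        n_mod = len(members)
        if n_flagged == 0:
            pval = 1.0
        else:
            pval = float(stats.hypergeom.sf(k - 1, n_total, n_flagged, n_mod))
        rows.append(
            {
                "module": mod,
                "size": n_mod,
                "n_flagged": k,
                "expected": n_mod * n_flagged / n_total if n_total else 0.0,
                "p_value": pval,
            }
        )
    df = pd.DataFrame(rows).set_index("module")
    df["p_adjusted"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    df["enriched"] = df["p_adjusted"] <= alpha
    return df


# ---------------------------------------------------------------------------
# report assembly and comparison


@dataclass
class TopologyReport:
    """The full metric battery for one network."""

    n_nodes: int
    n_edges: int
    degree_mean: float
    degree_sd: float
    path_length: PathLengthStats | None
    betweenness_values: dict[str, float]
    assortativity: float
    ect: float
    ect_normalization: str
    pep: float
    census: ComponentCensus
    partition: ModulePartition | None
    estrada: EstradaClassification | None
    robustness: dict[str, RobustnessCurve] = field(default_factory=dict)

    def summary(self) -> dict[str, float | str | int]:
        out: dict[str, float | str | int] = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "degree_mean": self.degree_mean,
            "degree_sd": self.degree_sd,
            "assortativity_phylum": self.assortativity,
            "ect": self.ect,
            "ect_normalization": self.ect_normalization,
            "pep": self.pep,
            "lcc_fraction": self.census.lcc_fraction,
        }
        if self.path_length is not None:
            out["path_length_mean"] = self.path_length.mean
            out["path_length_sd"] = self.path_length.sd
        if self.partition is not None:
            out["n_modules"] = self.partition.n_modules
            out["modularity"] = self.partition.modularity
            out["realized_modularity"] = self.partition.realized_modularity
        if self.estrada is not None:
            out["estrada_class"] = self.estrada.estrada_class
        for name, curve in self.robustness.items():
            out[f"robustness_auc_{name}"] = curve.area_under_curve
        return out


def topology_report(
    net,
    seed: int = 0,
    with_robustness: bool = True,
    n_random_repeats: int = 100,
    ect_normalization: str = "mean",
) -> TopologyReport:
    """Compute the whole topology battery for one network."""
    g = _as_graph(net)
    dm, ds = degree_stats(g)
    census = component_census(g)
    try:
        pl = path_length_stats(g)
    except ValueError:
        pl = None
    btw = betweenness(g, normalized=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        assort = assortativity_by_attribute(g, "phylum")
        ect = expected_commute_time(g, normalization=ect_normalization, restrict_to_lcc=True)
        pep = positive_edge_percentage(g)
    partition = None
    estrada = None
    if g.number_of_edges() > 0:
        partition = modularity_partition(g, seed=seed)
        if census.lcc_size >= 2:
            try:
                estrada = estrada_classify(g)
            except ValueError:
                estrada = None
    robustness = {}
    if with_robustness:
        for strat in ("betweenness", "degree", "random"):
            robustness[strat] = attack_robustness(
                g, strategy=strat, recompute=True, seed=seed,
                n_random_repeats=n_random_repeats,
            )
    return TopologyReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        degree_mean=dm,
        degree_sd=ds,
        path_length=pl,
        betweenness_values=btw,
        assortativity=assort,
        ect=ect,
        ect_normalization=ect_normalization,
        pep=pep,
        census=census,
        partition=partition,
        estrada=estrada,
        robustness=robustness,
    )


def welch_test_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch's unequal-variances t-test with Satterthwaite df."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)


def compare_networks(report_a: TopologyReport, report_b: TopologyReport) -> pd.DataFrame:
    """Side-by-side metric table with Welch tests and deltas.

    Degree and pairwise-distance distributions are compared with Welch's
    unequal-variances t-test (from their summary statistics); global scalars
    (ECT, PEP, realized modularity, robustness AUCs) are reported as
    differences (B - A).
    """
    rows = []

    def add(metric, a, b, tstat=None, pval=None):
        rows.append(
            {
                "metric": metric,
                "network_a": a,
                "network_b": b,
                "delta": (b - a) if isinstance(a, (int, float)) and isinstance(b, (int, float))
                and not (isinstance(a, float) and np.isnan(a)) else np.nan,
                "welch_t": tstat,
                "p_value": pval,
            }
        )

    t, p = welch_test_from_stats(
        report_a.degree_mean, max(report_a.degree_sd, 1e-12), report_a.n_nodes,
        report_b.degree_mean, max(report_b.degree_sd, 1e-12), report_b.n_nodes,
    )
    add("degree_mean", report_a.degree_mean, report_b.degree_mean, t, p)
    if report_a.path_length and report_b.path_length:
        t, p = welch_test_from_stats(
            report_a.path_length.mean, max(report_a.path_length.sd, 1e-12),
            report_a.path_length.n_connected_pairs,
            report_b.path_length.mean, max(report_b.path_length.sd, 1e-12),
            report_b.path_length.n_connected_pairs,
        )
        add("path_length_mean", report_a.path_length.mean, report_b.path_length.mean, t, p)
    add("ect", report_a.ect, report_b.ect)
    add("pep", report_a.pep, report_b.pep)
    if report_a.partition and report_b.partition:
        add(
            "realized_modularity",
            report_a.partition.realized_modularity,
            report_b.partition.realized_modularity,
        )
    add("assortativity_phylum", report_a.assortativity, report_b.assortativity)
    for strat in sorted(set(report_a.robustness) & set(report_b.robustness)):
        add(
            f"robustness_auc_{strat}",
            report_a.robustness[strat].area_under_curve,
            report_b.robustness[strat].area_under_curve,
        )
    if report_a.estrada and report_b.estrada:
        add("estrada_class", report_a.estrada.estrada_class, report_b.estrada.estrada_class)
    return pd.DataFrame(rows).set_index("metric")
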
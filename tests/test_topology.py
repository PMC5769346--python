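"""Topology battery: hand-checkable fixtures plus brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from crossdomnet import topology as T
from .conftest import random_connected_graph


# ---------------------------------------------------------------------------
# oracles


def brute_force_betweenness(g):
    """Exhaustive shortest-path enumeration betweenness, normalized."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: s / norm for v, s in score.items()}


def mixing_matrix_assortativity(g, attr):
    """Newman's categorical assortativity from the mixing matrix."""
    cats = sorted({d[attr] for _, d in g.nodes(data=True)})
    idx = {c: i for i, c in enumerate(cats)}
    e = np.zeros((len(cats), len(cats)))
    for u, v in g.edges:
        a, b = idx[g.nodes[u][attr]], idx[g.nodes[v][attr]]
        e[a, b] += 1
        e[b, a] += 1
    e /= e.sum()
    tr = np.trace(e)
    s = (e @ e).sum()
    return (tr - s) / (1 - s)


def montecarlo_commute_time(g, n_walks, rng):
    """Average commute time over pairs by simulating random walks."""
    nodes = list(g.nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    neighbors = [np.array([pos[w] for w in g.neighbors(v)]) for v in nodes]
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    per_pair = max(1, n_walks // (2 * len(pairs)))
    total = 0.0
    for i, j in pairs:
        for a, b in ((i, j), (j, i)):  # hit(a->b) + hit(b->a) = commute
            state = np.full(per_pair, a)
            steps = np.zeros(per_pair)
            active = np.ones(per_pair, dtype=bool)
            while active.any():
                moving = np.flatnonzero(active)
                nxt = np.array(
                    [neighbors[s][rng.integers(len(neighbors[s]))] for s in state[moving]]
                )
                state[moving] = nxt
                steps[moving] += 1
                active[moving] = nxt != b
            total += steps.mean()
    return total / len(pairs)


# ---------------------------------------------------------------------------


class TestComponentsDegreesPaths:
    def test_census_with_singletons(self):
        g = nx.path_graph(302)
        g.add_nodes_from(["x1", "x2", "x3"])
        census = T.component_census(g)
        assert census.sizes == [302, 1, 1, 1]
        assert f"{census.lcc_fraction:.2%}" == "99.02%"  # 302/305

    def test_edgeless_graph_is_all_singletons(self):
        census = T.component_census(nx.empty_graph(5))
        assert census.n_singletons == 5

    @pytest.mark.parametrize(
        "graph, mean, sd",
        [(nx.complete_graph(5), 4.0, 0.0), (nx.star_graph(4), 8 / 5, None)],
    )
    def test_degree_stats_on_fixtures(self, graph, mean, sd):
        m, s = T.degree_stats(graph)
        assert m == pytest.approx(mean)
        if sd is not None:
            assert s == pytest.approx(sd)

    def test_degree_stats_match_edge_count(self):
        g = nx.gnp_random_graph(20, 0.3, seed=1)
        m, _ = T.degree_stats(g)
        assert m == pytest.approx(2 * g.number_of_edges() / 20)

    def test_betweenness_path_center_and_complete(self):
        assert T.betweenness(nx.path_graph(3))[1] == pytest.approx(1.0)
        assert all(v == 0 for v in T.betweenness(nx.complete_graph(5)).values())

    def test_betweenness_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_connected_graph(rng)
            mine = T.betweenness(g)
            oracle = brute_force_betweenness(g)
            for v in g.nodes:
                assert mine[v] == pytest.approx(oracle[v], abs=1e-12)

    def test_path_length_p4_and_complete(self):
        assert T.path_length_stats(nx.path_graph(4)).mean == pytest.approx(5 / 3)
        assert T.path_length_stats(nx.complete_graph(6)).mean == pytest.approx(1.0)

    def test_disconnected_pairs_counted_not_averaged(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        stats = T.path_length_stats(g)
        assert stats.n_disconnected_pairs == 6
        assert np.isfinite(stats.mean)

    def test_domain_filtered_paths_may_cross_other_domain(self):
        g = nx.path_graph(3)  # 0 - 1 - 2
        nx.set_node_attributes(g, {0: "A", 1: "B", 2: "A"}, "domain")
        stats = T.path_length_stats(g, domain="A")
        assert stats.mean == pytest.approx(2.0)  # route through the B node


class TestModularity:
    def _two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        return g

    def test_two_cliques_split_cleanly(self):
        part = T.modularity_partition(self._two_cliques())
        assert part.n_modules == 2
        assert part.realized_modularity == pytest.approx(12 / 13)
        mods = {part.assignment[n] for n in range(4)}
        assert len(mods) == 1  # first clique in one module

    def test_modularity_score_cross_checked_with_networkx(self):
        g = nx.gnp_random_graph(30, 0.15, seed=5)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        part = T.modularity_partition(g)
        comms = [set(part.members(m)) for m in range(part.n_modules)]
        q_nx = nx.community.modularity(g, comms, weight=None)
        assert part.modularity == pytest.approx(q_nx, abs=1e-12)
        # and not far below a greedy baseline
        greedy = nx.community.greedy_modularity_communities(g, weight=None)
        q_greedy = nx.community.modularity(g, greedy, weight=None)
        assert part.modularity >= q_greedy - 0.05

    def test_deterministic_across_runs(self):
        g = nx.gnp_random_graph(25, 0.2, seed=7)
        a = T.modularity_partition(g)
        b = T.modularity_partition(g)
        assert a.assignment == b.assignment

    def test_realized_modularity_bounds(self):
        part = T.modularity_partition(self._two_cliques())
        assert 0.0 <= part.realized_modularity <= 1.0
        # equals 1 iff no inter-module edges: drop the bridge
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        g.remove_edge(0, 4)
        g.add_edge(0, 1)  # keep connected component analysis on one clique
        part2 = T.modularity_partition(g, on_lcc=True)
        assert part2.realized_modularity == 1.0


class TestAssortativity:
    def test_monophyletic_cliques_fully_assortative(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        for n in g.nodes:
            g.nodes[n]["phylum"] = "A" if n < 4 else "B"
        assert T.assortativity_by_attribute(g) == pytest.approx(1.0)

    def test_complete_bipartite_fully_disassortative(self):
        g = nx.complete_bipartite_graph(3, 4)
        for n in g.nodes:
            g.nodes[n]["phylum"] = "A" if n < 3 else "B"
        assert T.assortativity_by_attribute(g) == pytest.approx(-1.0)

    def test_matches_mixing_matrix_oracle(self):
        rng = np.random.default_rng(1)
        g = random_connected_graph(rng, n_max=10)
        for n in g.nodes:
            g.nodes[n]["phylum"] = ["A", "B", "C"][n % 3]
        mine = T.assortativity_by_attribute(g)
        assert mine == pytest.approx(mixing_matrix_assortativity(g, "phylum"), abs=1e-12)

    def test_single_category_undefined(self):
        g = nx.complete_graph(4)
        nx.set_node_attributes(g, "A", "phylum")
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(T.assortativity_by_attribute(g))


class TestCommuteTime:
    def test_path_p3(self):
        assert T.expected_commute_time(nx.path_graph(3)) == pytest.approx(16 / 3)
        assert T.expected_commute_time(nx.path_graph(3), "sum") == pytest.approx(16.0)

    def test_complete_k3(self):
        assert T.expected_commute_time(nx.complete_graph(3)) == pytest.approx(4.0)

    def test_matches_random_walk_oracle(self):
        rng = np.random.default_rng(3)
        for seed in range(3):
            g = random_connected_graph(rng, n_max=6)
            spectral = T.expected_commute_time(g)
            mc = montecarlo_commute_time(g, 40000, np.random.default_rng(seed))
            assert mc == pytest.approx(spectral, rel=0.05)

    def test_total_resistance_monotone_under_edge_addition(self):
        """Rayleigh: adding an edge can only lower every effective resistance."""
        g = nx.path_graph(6)
        missing = [(u, v) for u, v in itertools.combinations(g.nodes, 2)
                   if not g.has_edge(u, v)]
        def total_resistance(h):
            mu = np.linalg.eigvalsh(nx.laplacian_matrix(h).toarray().astype(float))[1:]
            return h.number_of_nodes() * np.sum(1.0 / mu)
        base = total_resistance(g)
        for u, v in missing[:5]:
            h = g.copy()
            h.add_edge(u, v)
            assert total_resistance(h) <= base + 1e-9

    def test_disconnected_requires_lcc_opt_in(self):
        g = nx.disjoint_union(nx.path_graph(3), nx.path_graph(2))
        with pytest.raises(ValueError):
            T.expected_commute_time(g)
        with pytest.warns(UserWarning):
            val = T.expected_commute_time(g, restrict_to_lcc=True)
        assert val == pytest.approx(16 / 3)


class TestAttackRobustness:
    def test_star_hub_removal(self):
        curve = T.attack_robustness(nx.star_graph(4), strategy="degree")
        assert curve.fraction_in_lcc[0] == 1.0
        assert curve.fraction_in_lcc[1] == pytest.approx(0.2)

    def test_complete_graph_never_fragments(self):
        curve = T.attack_robustness(nx.complete_graph(5), strategy="betweenness")
        np.testing.assert_allclose(curve.fraction_in_lcc, [1, 0.8, 0.6, 0.4, 0.2, 0.0])

    def test_random_strategy_reproducible(self):
        g = nx.gnp_random_graph(15, 0.3, seed=2)
        a = T.attack_robustness(g, "random", seed=4, n_random_repeats=10)
        b = T.attack_robustness(g, "random", seed=4, n_random_repeats=10)
        np.testing.assert_array_equal(a.fraction_in_lcc, b.fraction_in_lcc)

    def test_curves_monotone_non_increasing(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            g = random_connected_graph(rng)
            for strat in ("betweenness", "degree"):
                curve = T.attack_robustness(g, strat)
                assert (np.diff(curve.fraction_in_lcc) <= 1e-12).all()

    def test_star_random_attack_beats_targeted(self):
        g = nx.star_graph(9)
        targeted = T.attack_robustness(g, "degree")
        rand = T.attack_robustness(g, "random", seed=0, n_random_repeats=50)
        assert rand.area_under_curve >= targeted.area_under_curve

    def test_auc_in_unit_interval(self):
        curve = T.attack_robustness(nx.path_graph(6), "betweenness")
        assert 0.0 <= curve.area_under_curve <= 1.0


class TestPositiveEdgePercentage:
    def test_half_positive(self):
        g = nx.Graph()
        for k, w in enumerate([0.2, 0.1, -0.3, -0.4]):
            g.add_edge(f"a{k}", f"b{k}", partial_correlation=w)
        assert T.positive_edge_percentage(g) == pytest.approx(0.5)

    def test_all_positive(self):
        g = nx.Graph()
        g.add_edge(0, 1, partial_correlation=0.4)
        assert T.positive_edge_percentage(g) == 1.0

    def test_edgeless_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(T.positive_edge_percentage(nx.empty_graph(3)))


class TestEstrada:
    def _oracle_deviations(self, g):
        nodes = sorted(g.nodes)
        a = nx.to_numpy_array(g, nodelist=nodes)
        sc_odd = np.diag((expm(a) - expm(-a)) / 2)
        evals, evecs = np.linalg.eigh(a)
        v1 = np.abs(evecs[:, -1])
        return np.log10(sc_odd) - np.log10(np.sinh(evals[-1]) * v1**2)

    def test_vertex_transitive_is_class_i(self):
        # odd cycle: vertex-transitive and non-bipartite (even cycles have a
        # symmetric spectrum, where odd-walk centrality vanishes)
        for g in (nx.complete_graph(3), nx.cycle_graph(5)):
            cls = T.estrada_classify(g)
            assert cls.estrada_class == "I"
            devs = np.array(list(cls.deviations.values()))
            assert devs.max() - devs.min() < 1e-9

    def test_bridged_dense_clusters_are_modular_class_ii(self):
        g = nx.disjoint_union(
            nx.gnp_random_graph(10, 0.9, seed=1), nx.gnp_random_graph(10, 0.9, seed=2)
        )
        g.add_edge(0, 10)
        assert T.estrada_classify(g).estrada_class == "II"

    def test_clique_with_pendants_is_core_periphery_class_iii(self):
        g = nx.complete_graph(8)
        k = 8
        for hub in range(6):
            for _ in range(3):
                g.add_edge(hub, k)
                k += 1
        assert T.estrada_classify(g).estrada_class == "III"

    def test_deviations_match_matrix_exponential_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            g = random_connected_graph(rng)
            try:
                cls = T.estrada_classify(g)
            except ValueError:  # bipartite-like spectrum, oracle also degenerate
                continue
            oracle = self._oracle_deviations(g)
            mine = np.array([cls.deviations[n] for n in sorted(g.nodes)])
            np.testing.assert_allclose(mine, oracle, atol=1e-9)

    def test_invariant_under_relabeling(self):
        g = nx.disjoint_union(
            nx.gnp_random_graph(8, 0.85, seed=3), nx.gnp_random_graph(8, 0.85, seed=4)
        )
        g.add_edge(0, 8)
        relabeled = nx.relabel_nodes(g, {n: f"node_{n}" for n in g.nodes})
        assert (
            T.estrada_classify(g).estrada_class
            == T.estrada_classify(relabeled).estrada_class
        )


class TestKeystone:
    def test_star_hub_maximal_in_both(self):
        df = T.keystone_scatter(nx.star_graph(4))
        hub = df.loc[0]
        assert hub["is_max_degree"] and hub["is_max_betweenness"]

    def test_vertex_transitive_all_tied(self):
        df = T.keystone_scatter(nx.cycle_graph(5))
        assert df["is_max_degree"].all()
        assert df["is_max_betweenness"].all()

    def test_abundance_and_prevalence_columns(self):
        from .conftest import make_table

        g = nx.path_graph(2)
        g = nx.relabel_nodes(g, {0: "otu0", 1: "otu1"})
        counts = make_table([[8, 2], [0, 10]])
        df = T.keystone_scatter(g, counts=counts)
        assert df.loc["otu0", "max_relative_abundance"] == pytest.approx(0.8)
        assert df.loc["otu0", "prevalence"] == pytest.approx(0.5)
        assert df.loc["otu1", "prevalence"] == pytest.approx(1.0)


class TestExclusiveSubnetworks:
    def _setup(self):
        from .conftest import make_table

        counts = make_table(
            [[5, 0, 3], [2, 4, 1], [0, 6, 2]],
            sample_ids=["h1", "h2", "c1"],
        )
        labels = {"h1": "HIV+", "h2": "HIV+", "c1": "HIV-"}
        g = nx.path_graph(["otu0", "otu1", "otu2"])
        return g, counts, labels

    def test_exclusive_definition_is_strict(self):
        g, counts, labels = self._setup()
        result = T.status_exclusive_subnetworks(g, counts, labels, "HIV+")
        # otu0 appears only in h1/h2; otu1 has a read in c1 so it is excluded
        assert result.exclusive_nodes == ["otu0"]
        assert set(result.subnetwork.nodes) == {"otu0", "otu1"}  # closed neighborhood

    def test_no_exclusives_returns_empty(self):
        g, counts, labels = self._setup()
        result = T.status_exclusive_subnetworks(g, counts, labels, "UNKNOWN")
        assert result.exclusive_nodes == []
        assert result.subnetwork.number_of_nodes() == 0

    def test_isolated_exclusives_stay_singletons(self):
        from .conftest import make_table

        counts = make_table([[3, 1], [0, 1]], sample_ids=["a", "b"])
        labels = {"a": "G", "b": "H"}
        g = nx.empty_graph(0)
        g.add_nodes_from(["otu0", "otu1"])
        result = T.status_exclusive_subnetworks(g, counts, labels, "G")
        assert result.exclusive_nodes == ["otu0"]
        assert result.census.n_singletons == 1


class TestModuleEnrichment:
    def _partition(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        return T.modularity_partition(g)

    def test_concentrated_flags_have_smallest_p(self):
        part = self._partition()
        table = T.module_enrichment(part, set(part.members(0)))
        assert table.loc[0, "p_value"] == table["p_value"].min()
        assert table.loc[0, "p_value"] < 0.05

    def test_uniform_flags_not_enriched(self):
        part = self._partition()
        flagged = {part.members(0)[0], part.members(1)[0]}
        table = T.module_enrichment(part, flagged)
        assert not table["enriched"].any()

    def test_empty_flags_all_p_one(self):
        part = self._partition()
        table = T.module_enrichment(part, set())
        assert (table["p_value"] == 1.0).all()

    def test_hypergeometric_oracle(self):
        from scipy.stats import hypergeom

        part = self._partition()
        flagged = set(part.members(0))  # 5 flags concentrated in one module of 5
        table = T.module_enrichment(part, flagged)
        n_total = len(part.assignment)
        expect = hypergeom.sf(4, n_total, 5, 5)
        assert table.loc[0, "p_value"] == pytest.approx(expect)


class TestCompareNetworks:
    def _annotated(self, g):
        for n in g.nodes:
            g.nodes[n]["phylum"] = "A" if int(n) % 2 else "B"
            g.nodes[n]["domain"] = "16S"
        for u, v in g.edges:
            g[u][v]["partial_correlation"] = 0.2
        return g

    def test_identical_networks_all_deltas_zero(self):
        g = self._annotated(nx.gnp_random_graph(15, 0.3, seed=3))
        rep = T.topology_report(g, with_robustness=False)
        table = T.compare_networks(rep, rep)
        deltas = table["delta"].dropna()
        np.testing.assert_allclose(deltas, 0.0, atol=1e-12)
        assert table.loc["degree_mean", "p_value"] == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        m1, s1, n1 = 3.176, 1.094, 300
        m2, s2, n2 = 2.588, 0.734, 250
        t, p = T.welch_test_from_stats(m1, s1, n1, m2, s2, n2)
        se = np.sqrt(s1**2 / n1 + s2**2 / n2)
        t_hand = (m1 - m2) / se
        df_hand = se**4 / (
            (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
        )
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_denser_network_is_better_connected(self):
        """Adding cross-links to a sparse backbone shortens paths and lowers
        the per-pair commute time on the same node set."""
        base = self._annotated(nx.cycle_graph(12))
        dense = base.copy()
        for k in range(0, 12, 2):
            dense.add_edge(k, (k + 5) % 12, partial_correlation=0.2)
        rep_a = T.topology_report(dense, with_robustness=False)
        rep_b = T.topology_report(base, with_robustness=False)
        assert rep_a.ect <= rep_b.ect
        assert rep_a.path_length.mean <= rep_b.path_length.mean
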
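"""Connectivity graphs: binning, Pearson maps, topology, hubs, rich club."""
import numpy as np
import pytest

import meanet as m
from meanet.graph import null_adjacencies
from meanet.types import ConnectivityGraph, TopologySummary


def adjacency_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return adj


def graph_from_adj(adj):
    n = adj.shape[0]
    corr = np.where(adj, 0.9, 0.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityGraph(corr=corr, adj=adj, threshold=0.5)


def brute_force_topology(adj):
    """O(n^3) triangle enumeration and direct degree/edge counts."""
    n = adj.shape[0]
    degree = adj.sum(axis=1)
    n_edges = int(degree.sum() // 2)
    clustering = np.zeros(n)
    for i in range(n):
        tri = sum(
            1
            for j in range(n)
            for k in range(j + 1, n)
            if adj[i, j] and adj[i, k] and adj[j, k]
        )
        if degree[i] >= 2:
            clustering[i] = 2.0 * tri / (degree[i] * (degree[i] - 1))
    return n_edges, degree, clustering


def brute_force_phi(adj, k):
    degree = adj.sum(axis=1)
    nodes = [i for i in range(adj.shape[0]) if degree[i] > k]
    if len(nodes) < 2:
        return None
    e = sum(1 for a in range(len(nodes)) for b in range(a + 1, len(nodes)) if adj[nodes[a], nodes[b]])
    return 2.0 * e / (len(nodes) * (len(nodes) - 1))


class TestBinCounts:
    def test_empty_trains_all_zero(self, trains_factory):
        counts = m.bin_counts(trains_factory({}, duration=1.0), 0.025)
        assert counts.shape == (64, 40)
        assert counts.sum() == 0

    def test_half_open_bin_convention(self, trains_factory):
        counts = m.bin_counts(trains_factory({0: [0.03]}, duration=0.1), 0.025)
        assert counts[0, 1] == 1 and counts.sum() == 1

    def test_row_sums_conserve_spike_counts(self, rng, trains_factory):
        spikes = {e: list(rng.uniform(0, 9.99, rng.integers(0, 50))) for e in range(64)}
        trains = trains_factory(spikes, duration=10.0)
        counts = m.bin_counts(trains)
        np.testing.assert_array_equal(counts.sum(axis=1), trains.counts())


class TestPearsonConnectivity:
    def test_identical_rows_fully_correlated(self):
        row = np.array([0, 1, 2, 0, 3, 1], dtype=float)
        g = m.pearson_connectivity(np.vstack([row, row]))
        assert g.corr[0, 1] == pytest.approx(1.0)

    def test_zero_variance_row_convention(self):
        g = m.pearson_connectivity(np.vstack([np.zeros(6), np.arange(6.0)]))
        assert g.corr[0, 1] == 0.0
        assert g.corr[0, 0] == 1.0  # diagonal pinned to 1 regardless

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            m.pearson_connectivity(np.ones((3, 1)))

    def test_matches_hand_computed_formula_on_toy_matrix(self):
        counts = np.array(
            [
                [2, 0, 1, 3, 0, 1],
                [0, 1, 1, 2, 1, 0],
                [5, 0, 0, 1, 2, 2],
                [1, 1, 1, 1, 1, 3],
            ],
            dtype=float,
        )
        g = m.pearson_connectivity(counts)
        n = counts.shape[0]
        for i in range(n):
            for j in range(n):
                xi, xj = counts[i] - counts[i].mean(), counts[j] - counts[j].mean()
                expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
                if i == j:
                    expected = 1.0
                assert g.corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_common_bin_permutation(self, rng):
        counts = rng.poisson(1.0, (8, 200)).astype(float)
        perm = rng.permutation(200)
        g1 = m.pearson_connectivity(counts)
        g2 = m.pearson_connectivity(counts[:, perm])
        np.testing.assert_allclose(g1.corr, g2.corr, atol=1e-12)


class TestThresholdGraph:
    def test_all_zero_correlation_gives_empty_graph(self):
        corr = np.eye(5)
        g = m.threshold_graph(ConnectivityGraph(corr=corr), threshold=0.3)
        assert g.adj.sum() == 0

    def test_edges_require_threshold_and_distinctness(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.5
        corr[1, 2] = corr[2, 1] = 0.2
        g = m.threshold_graph(ConnectivityGraph(corr=corr), threshold=0.3)
        assert g.adj[0, 1] and not g.adj[1, 2] and not g.adj.diagonal().any()

    def test_inactive_electrodes_excluded(self):
        corr = np.full((4, 4), 0.9)
        np.fill_diagonal(corr, 1.0)
        mask = np.array([True, True, False, True])
        g = m.threshold_graph(ConnectivityGraph(corr=corr), 0.3, active_mask=mask)
        assert not g.adj[2].any() and g.adj[0, 1] and g.adj[0, 3]

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            m.threshold_graph(ConnectivityGraph(corr=np.eye(2)), threshold=1.0)


class TestTopology:
    def test_complete_graph_k4(self):
        adj = adjacency_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        topo = m.topology(graph_from_adj(adj))
        assert topo.n_edges == 6
        np.testing.assert_array_equal(topo.degree, 3)
        np.testing.assert_allclose(topo.clustering, 1.0)

    def test_star_graph(self):
        adj = adjacency_from_edges(6, [(0, j) for j in range(1, 6)])
        topo = m.topology(graph_from_adj(adj))
        assert topo.n_edges == 5
        np.testing.assert_allclose(topo.clustering, 0.0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            adj = np.triu(rng.random((12, 12)) < 0.35, 1)
            adj = adj | adj.T
            topo = m.topology(graph_from_adj(adj))
            n_edges, degree, clustering = brute_force_topology(adj)
            assert topo.n_edges == n_edges
            np.testing.assert_array_equal(topo.degree, degree)
            np.testing.assert_allclose(topo.clustering, clustering, atol=1e-12)

    def test_edge_count_equals_half_degree_sum(self, rng):
        adj = np.triu(rng.random((20, 20)) < 0.2, 1)
        adj = adj | adj.T
        topo = m.topology(graph_from_adj(adj))
        assert topo.n_edges * 2 == topo.degree.sum()


class TestHubNodes:
    def test_regular_graph_has_no_hubs(self):
        adj = adjacency_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])  # cycle
        assert m.topology(graph_from_adj(adj)).hubs == []

    def test_star_center_is_unique_hub(self):
        adj = adjacency_from_edges(10, [(0, j) for j in range(1, 10)])
        assert m.topology(graph_from_adj(adj)).hubs == [0]

    def test_criterion_direct_evaluation(self, rng):
        adj = np.triu(rng.random((20, 20)) < 0.15, 1)
        adj = adj | adj.T
        topo = m.topology(graph_from_adj(adj))
        deg = topo.degree
        connected = deg[deg > 0]
        expected = [int(i) for i in np.flatnonzero(deg > connected.mean() + connected.std())]
        assert topo.hubs == expected


class TestRichClub:
    def test_complete_graph_phi_is_one(self):
        adj = adjacency_from_edges(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        rc = m.rich_club(graph_from_adj(adj), n_null=5, seed=0)
        assert rc  # k = 0..4 all reported
        for point in rc.values():
            assert point.phi == pytest.approx(1.0)

    def test_empty_graph_gives_empty_map(self):
        adj = np.zeros((8, 8), dtype=bool)
        assert m.rich_club(graph_from_adj(adj), n_null=5, seed=0) == {}

    def test_phi_matches_brute_force_on_10_node_graphs(self, rng):
        for _ in range(10):
            adj = np.triu(rng.random((10, 10)) < 0.4, 1)
            adj = adj | adj.T
            rc = m.rich_club(graph_from_adj(adj), n_null=3, seed=1)
            for k, point in rc.items():
                assert point.phi == pytest.approx(brute_force_phi(adj, k))

    def test_null_preserves_degree_sequence(self, rng):
        adj = np.triu(rng.random((14, 14)) < 0.3, 1)
        adj = adj | adj.T
        degree = adj.sum(axis=1)
        for null in null_adjacencies(adj, n_null=20, seed=3):
            np.testing.assert_array_equal(null.sum(axis=1), degree)

    def test_null_mean_consistent_across_independent_samplings(self, rng):
        # Monte-Carlo consistency of the swap-space mean on a small graph
        adj = np.triu(rng.random((6, 6)) < 0.6, 1)
        adj = adj | adj.T
        g = graph_from_adj(adj)
        rc_a = m.rich_club(g, n_null=300, seed=5)
        rc_b = m.rich_club(g, n_null=300, seed=99)
        for k in rc_a:
            assert rc_a[k].phi_null_mean == pytest.approx(rc_b[k].phi_null_mean, abs=0.05)

    def test_normalization_near_one_for_random_graph(self, rng):
        # an ER-like graph is its own null: phi_norm ~ 1 at well-populated k
        adj = np.triu(rng.random((24, 24)) < 0.25, 1)
        adj = adj | adj.T
        rc = m.rich_club(graph_from_adj(adj), n_null=60, seed=7)
        degree = adj.sum(axis=1)
        for k, point in rc.items():
            if (degree > k).sum() >= 10:
                assert point.phi_norm == pytest.approx(1.0, abs=0.3)

    def test_seeded_determinism(self, rng):
        adj = np.triu(rng.random((12, 12)) < 0.3, 1)
        adj = adj | adj.T
        g = graph_from_adj(adj)
        rc_a = m.rich_club(g, n_null=10, seed=42)
        rc_b = m.rich_club(g, n_null=10, seed=42)
        assert rc_a == rc_b


class TestDevelopmentalConnectivity:
    def test_mature_network_has_more_edges(self):
        # synchrony growth drives edge formation (majority over seeds)
        wins = 0
        for seed in range(5):
            counts = {}
            for stage in ("DAI8", "DAI21"):
                trains = m.simulate_spiketrains(m.make_preset(stage), 600.0, seed=seed)
                _, mask = m.active_electrodes(trains)
                _, topo = m.connectivity_pipeline(trains, active_mask=mask)
                counts[stage] = topo.n_edges
            wins += counts["DAI21"] > counts["DAI8"]
        assert wins >= 4
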
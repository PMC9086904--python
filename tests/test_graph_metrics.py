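import networkx as nx
import numpy as np
import pytest

from morphnet import _kernels
from morphnet.graph_metrics import (BinaryGraph, ThresholdSpec, global_metrics,
                                    metric_auc, nodal_metrics,
                                    normalized_metrics, sweep_metrics,
                                    threshold_graph)
from morphnet.kls_network import build_network
from morphnet.roi_io import MorphNetwork

import oracles


def random_weight_matrix(rng, n):
    m = rng.uniform(0.001, 0.999, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestThresholdSpec:
    def test_default_has_26_levels(self):
        spec = ThresholdSpec()
        levels = spec.levels
        assert levels.size == 26
        assert levels[0] == pytest.approx(0.10)
        assert levels[-1] == pytest.approx(0.35)

    @pytest.mark.parametrize("kw", [
        {"s_min": 0.0}, {"s_min": 0.4, "s_max": 0.3}, {"s_max": 1.0},
        {"s_step": 0.0}, {"s_step": -0.1},
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            ThresholdSpec(**kw)


class TestThresholdGraph:
    def test_expected_edge_count_at_116(self, rng):
        # round(0.10 * 116*115/2) = round(667.0) = 667
        m = random_weight_matrix(rng, 116)
        bg = threshold_graph(m, 0.10)
        assert bg.n_edges == 667

    def test_saturation_gives_complete_graph(self, rng):
        m = random_weight_matrix(rng, 8)
        bg = threshold_graph(m, 0.999)
        assert bg.n_edges == 28
        assert np.all(bg.adjacency + np.eye(8, dtype=np.uint8) == 1)

    def test_top_k_matches_sorting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 12))
            m = random_weight_matrix(rng, n)
            s = float(rng.uniform(0.1, 0.8))
            bg = threshold_graph(m, s)
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
            pairs.sort(key=lambda p: (-m[p], p))
            k = round(s * len(pairs))
            expected = set(pairs[:k])
            got = {(i, j) for i, j in zip(*np.nonzero(np.triu(bg.adjacency, 1)))}
            assert got == expected

    def test_zero_edges_rejected(self, rng):
        with pytest.raises(ValueError, match="0 edges"):
            threshold_graph(random_weight_matrix(rng, 4), 0.01)

    def test_invalid_sparsity_rejected(self, rng):
        m = random_weight_matrix(rng, 5)
        for s in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                threshold_graph(m, s)

    def test_degree_sum_is_twice_edges(self, rng):
        m = random_weight_matrix(rng, 30)
        for s in (0.1, 0.2, 0.35):
            bg = threshold_graph(m, s)
            assert bg.adjacency.sum() == 2 * bg.n_edges


class TestGlobalMetrics:
    def test_complete_k4(self):
        adj = np.ones((4, 4), dtype=np.uint8) - np.eye(4, dtype=np.uint8)
        gm = global_metrics(adj)
        assert gm.Cp == 1.0
        assert gm.Lp == 1.0
        assert gm.Eglob == 1.0
        assert gm.Eloc == 1.0

    def test_path_graph(self):
        # A-B-C: ordered pairs (6): distances 1,1,1,1,2,2 -> Lp=4/3,
        # Eglob=(4*1+2*0.5)/6=5/6; no triangles -> Cp=0
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        gm = global_metrics(adj)
        assert gm.Cp == 0.0
        assert gm.Lp == pytest.approx(4 / 3)
        assert gm.Eglob == pytest.approx(5 / 6)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            global_metrics(np.zeros((4, 4), dtype=np.uint8))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            adj = oracles.random_adjacency(rng, n, p=float(rng.uniform(0.25, 0.9)))
            a = np.array(adj, dtype=np.uint8)
            gm = global_metrics(a)
            assert gm.Eglob == pytest.approx(oracles.global_efficiency(adj), abs=1e-10)
            assert gm.Eloc == pytest.approx(oracles.local_efficiency(adj), abs=1e-10)
            assert gm.Cp == pytest.approx(oracles.clustering(adj), abs=1e-10)
            assert gm.Lp == pytest.approx(oracles.char_path_length(adj), abs=1e-10)

    def test_matches_networkx(self, rng):
        for _ in range(5):
            g = nx.gnp_random_graph(25, 0.2, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0 or not nx.is_connected(g):
                continue
            adj = nx.to_numpy_array(g, dtype=np.uint8)
            gm = global_metrics(adj)
            assert gm.Eglob == pytest.approx(nx.global_efficiency(g), abs=1e-10)
            assert gm.Cp == pytest.approx(nx.average_clustering(g), abs=1e-10)
            assert gm.Lp == pytest.approx(
                nx.average_shortest_path_length(g), abs=1e-10)

    def test_eglob_monotone_under_edge_addition(self, rng):
        for _ in range(10):
            n = 8
            adj = np.array(oracles.random_adjacency(rng, n, p=0.3), dtype=np.uint8)
            missing = [(i, j) for i in range(n) for j in range(i + 1, n)
                       if not adj[i, j]]
            if not missing:
                continue
            i, j = missing[int(rng.integers(len(missing)))]
            before = global_metrics(adj).Eglob
            adj[i, j] = adj[j, i] = 1
            assert global_metrics(adj).Eglob >= before - 1e-12


class TestNodalMetrics:
    def test_star_betweenness(self):
        adj = np.zeros((5, 5), dtype=np.uint8)
        adj[0, 1:] = 1
        adj[1:, 0] = 1
        nm = nodal_metrics(adj)
        assert nm.betweenness[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.all(nm.betweenness[1:] == 0)

    def test_path_center(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
        nm = nodal_metrics(adj)
        assert nm.betweenness[1] == pytest.approx(1.0)
        assert nm.efficiency[1] == pytest.approx(1.0)
        assert list(nm.degree) == [1, 2, 1]

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            adj = oracles.random_adjacency(rng, n, p=float(rng.uniform(0.3, 0.9)))
            nm = nodal_metrics(np.array(adj, dtype=np.uint8))
            np.testing.assert_allclose(nm.betweenness, oracles.betweenness(adj),
                                       atol=1e-10)
            np.testing.assert_allclose(nm.degree, oracles.degrees(adj), atol=0)
            np.testing.assert_allclose(nm.efficiency,
                                       oracles.nodal_efficiency(adj), atol=1e-10)

    def test_matches_networkx_betweenness(self, rng):
        g = nx.gnp_random_graph(30, 0.15, seed=4)
        adj = nx.to_numpy_array(g, dtype=np.uint8)
        nm = nodal_metrics(adj)
        bc = nx.betweenness_centrality(g, normalized=False)
        np.testing.assert_allclose(nm.betweenness,
                                   [bc[i] for i in range(30)], atol=1e-9)

    def test_mean_nodal_efficiency_equals_eglob_when_connected(self, rng):
        for _ in range(10):
            adj = np.array(oracles.random_adjacency(rng, 8, p=0.6), dtype=np.uint8)
            gm = global_metrics(adj)
            if not gm.connected:
                continue
            nm = nodal_metrics(adj)
            assert nm.efficiency.mean() == pytest.approx(gm.Eglob, abs=1e-12)


class TestNormalizedMetrics:
    def test_complete_graph_is_rewiring_invariant(self):
        adj = np.ones((6, 6), dtype=np.uint8) - np.eye(6, dtype=np.uint8)
        gm = normalized_metrics(adj, n_nulls=5, seed=1)
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lambda_ == pytest.approx(1.0)
        assert gm.sigma == pytest.approx(1.0)
        assert gm.rewiring_failed

    def test_rewiring_preserves_degree_sequence(self, rng):
        adj = np.array(oracles.random_adjacency(rng, 12, p=0.4), dtype=np.uint8)
        deg = adj.sum(axis=1).copy()
        iu, ju = np.nonzero(np.triu(adj, 1))
        edges = np.column_stack([iu, ju]).astype(np.int64)
        swaps = _kernels.rewire(edges, adj, 10 * len(edges), 99)
        assert swaps > 0
        np.testing.assert_array_equal(adj, adj.T)
        np.testing.assert_array_equal(adj.sum(axis=1), deg)
        assert np.all(np.diag(adj) == 0)

    def test_watts_strogatz_networks_are_small_world(self):
        sigmas = []
        for seed in range(3):
            g = nx.watts_strogatz_graph(60, 10, 0.1, seed=seed)
            adj = nx.to_numpy_array(g, dtype=np.uint8)
            sigmas.append(normalized_metrics(adj, n_nulls=30, seed=seed).sigma)
        assert all(s > 1 for s in sigmas)

    def test_cp_lp_kernel_matches_oracle(self, rng):
        for _ in range(10):
            adj = np.array(oracles.random_adjacency(rng, 8, p=0.5), dtype=np.uint8)
            cp, lp, _ = _kernels.cp_lp(adj)
            assert cp == pytest.approx(oracles.clustering(adj), abs=1e-10)
            assert lp == pytest.approx(oracles.char_path_length(adj), abs=1e-10)


class TestMetricAuc:
    def test_constant_curve(self):
        spec = ThresholdSpec()
        assert metric_auc(np.full(26, 2.0), spec) == pytest.approx(0.5, abs=1e-12)

    def test_identity_curve(self):
        spec = ThresholdSpec()
        expected = (0.35 ** 2 - 0.10 ** 2) / 2
        assert metric_auc(spec.levels, spec) == pytest.approx(expected, abs=1e-12)

    def test_single_level_rejected(self):
        spec = ThresholdSpec(s_min=0.2, s_max=0.2)
        with pytest.raises(ValueError, match="at least 2"):
            metric_auc([1.0], spec)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metric_auc(np.ones(10), ThresholdSpec())


class TestSweep:
    @pytest.fixture()
    def network(self, tiny_cohort):
        from morphnet.kls_network import GridSpec
        return build_network(tiny_cohort.sample_sets[0], GridSpec(n_points=96))

    def test_26_levels_and_determinism(self, network):
        p1 = sweep_metrics(network, n_nulls=10, seed=3)
        p2 = sweep_metrics(network, n_nulls=10, seed=3)
        assert p1.thresholds.size == 26
        assert p1.global_table.equals(p2.global_table)
        for m in p1.auc_nodal:
            np.testing.assert_array_equal(p1.auc_nodal[m], p2.auc_nodal[m])

    def test_auc_consistency(self, network):
        spec = ThresholdSpec()
        panel = sweep_metrics(network, spec, n_nulls=5, seed=0)
        assert panel.auc_global["Eglob"] == pytest.approx(
            metric_auc(panel.global_table["Eglob"].to_numpy(), spec))
        np.testing.assert_allclose(
            panel.auc_nodal["degree"],
            [metric_auc(panel.nodal["degree"][:, i], spec)
             for i in range(network.n_rois)])

    def test_sigma_is_gamma_over_lambda(self, network):
        panel = sweep_metrics(network, n_nulls=5, seed=0)
        t = panel.global_table
        np.testing.assert_allclose(t["sigma"], t["gamma"] / t["lambda_"])
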
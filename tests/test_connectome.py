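"""Connectivity matrices, cost-efficiency thresholding, nodal measures."""

import numpy as np
import pytest

from gamebrain import connectome as cn
from conftest import (
    bf_betweenness,
    bf_clustering,
    bf_distances,
    bf_local_efficiency,
    bf_path_length,
    random_adjacency,
)


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


class TestCorrelationMatrix:
    def test_identical_and_negated_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        ts = np.column_stack([x, x, -x])
        r = cn.correlation_matrix(ts)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        ts = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 4.0]])
        r = cn.correlation_matrix(ts)
        assert r[0, 1] == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            cn.correlation_matrix(np.ones((2, 3)))  # too few time points
        ts = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="constant"):
            cn.correlation_matrix(ts)
        ts = np.random.default_rng(0).normal(size=(5, 3))
        ts[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cn.correlation_matrix(ts)


class TestNormalizeTractography:
    def test_row_division(self):
        counts = np.array([[0, 10, 0, 10], [10, 0, 0, 0],
                           [0, 0, 0, 0], [10, 0, 0, 0]], dtype=float)
        way = np.array([1000.0, 1000, 1000, 1000])
        m = cn.normalize_tractography(counts, way)
        assert m[0, 1] == pytest.approx((0.01 + 0.01) / 2)

    def test_zero_counts_give_zero_matrix(self):
        m = cn.normalize_tractography(np.zeros((3, 3)), np.ones(3))
        assert np.all(m == 0)

    def test_symmetrization_averages(self):
        counts = np.zeros((3, 3))
        counts[0, 1] = 20.0  # 0.02 after normalization
        counts[1, 0] = 40.0  # 0.04
        m = cn.normalize_tractography(counts, np.full(3, 1000.0))
        assert m[0, 1] == pytest.approx(0.03)
        assert m[1, 0] == pytest.approx(0.03)

    def test_errors(self):
        with pytest.raises(ValueError):
            cn.normalize_tractography(np.full((2, 2), -1.0), np.ones(2))
        with pytest.raises(ValueError):
            cn.normalize_tractography(np.ones((2, 2)), np.array([1.0, 0.0]))


class TestThresholdCostEfficiency:
    def test_three_node_chain_keeps_both_edges(self):
        """Brute-force enumeration: keeping both edges of the 0.9/0.8 chain
        maximizes E_glob - cost."""
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.8
        res = cn.threshold_cost_efficiency(w)
        assert res.adjacency.sum() // 2 == 2
        assert res.threshold == pytest.approx(0.8)
        # CE at both edges: E = (1 + 1 + 1/2)/3 = 5/6, cost = 2/3
        assert res.cost_efficiency == pytest.approx(5 / 6 - 2 / 3)

    def test_matches_brute_force_on_random_weighted(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            w = rng.random((n, n)) * (rng.random((n, n)) < 0.7)
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            if not w.any():
                continue
            res = cn.threshold_cost_efficiency(w)
            # exhaustive scan over all unique thresholds
            iu = np.triu_indices(n, 1)
            best = None
            n_pairs = n * (n - 1) / 2
            for t in np.unique(w[iu][w[iu] > 0])[::-1]:
                adj = w >= t
                np.fill_diagonal(adj, False)
                d = bf_distances(adj)
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.maximum(d, 1), 0.0)
                eg = inv.sum() / (n * (n - 1))
                ce = eg - adj[iu].sum() / n_pairs
                if best is None or ce > best[0] + 1e-12:
                    best = (ce, t)
            assert res.cost_efficiency == pytest.approx(best[0], abs=1e-9)

    def test_complete_graph_single_candidate(self):
        w = np.ones((4, 4)) - np.eye(4)
        res = cn.threshold_cost_efficiency(w)
        assert res.cost == pytest.approx(1.0)
        assert res.global_efficiency == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        n = 40
        w = rng.random((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        a = cn.threshold_cost_efficiency(w, max_candidates=15)
        b = cn.threshold_cost_efficiency(w**3, max_candidates=15)  # monotone map
        assert np.array_equal(a.adjacency, b.adjacency)
        c = cn.threshold_cost_efficiency(np.tanh(2 * w), max_candidates=15)
        assert np.array_equal(a.adjacency, c.adjacency)

    def test_errors(self):
        with pytest.raises(ValueError):
            cn.threshold_cost_efficiency(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            cn.threshold_cost_efficiency(np.ones((2, 2)))
        w = np.zeros((4, 4))
        w[0, 1] = 1.0  # asymmetric
        with pytest.raises(ValueError):
            cn.threshold_cost_efficiency(w)


class TestNodalMeasureExamples:
    def test_triangle(self):
        a = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert cn.clustering_coefficient(a, 0) == 1.0
        assert cn.local_efficiency(a, 0) == 1.0
        assert cn.nodal_path_length(a, 0) == 1.0

    def test_star_center(self):
        a = adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert cn.clustering_coefficient(a, 0) == 0.0
        assert cn.betweenness(a, 1) == 0.0  # leaf

    def test_k14_star_center_betweenness(self):
        a = adj_from_edges(5, [(0, i) for i in range(1, 5)])
        assert cn.betweenness(a, 0) == pytest.approx(6.0)  # C(4,2) pairs

    def test_four_node_example_clustering(self):
        a = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2)])
        assert cn.clustering_coefficient(a, 0) == pytest.approx(1 / 3)

    def test_star_plus_edge_local_efficiency(self):
        # K_{1,3} with extra edge {1,2}: center's neighbor pairs at
        # distances {1, inf, inf} -> (1+0+0)/3
        a = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2)])
        assert cn.local_efficiency(a, 0) == pytest.approx(1 / 3)

    def test_path_p3(self):
        a = adj_from_edges(3, [(0, 1), (1, 2)])
        assert cn.nodal_path_length(a, 0) == pytest.approx(1.5)
        assert cn.nodal_path_length(a, 1) == pytest.approx(1.0)
        assert cn.betweenness(a, 1) == pytest.approx(1.0)
        assert cn.local_efficiency(a, 1) == 0.0  # neighbors unconnected

    def test_cycle_c4(self):
        a = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        assert cn.nodal_path_length(a, 0) == pytest.approx(4 / 3)

    def test_isolated_node_flagged(self):
        a = adj_from_edges(4, [(0, 1)])
        L, flags = cn.nodal_path_length(a, return_flags=True)
        assert np.isnan(L[2]) and flags[2]
        assert L[0] == 1.0 and flags[0]  # some targets unreachable

    def test_asymmetric_adjacency_rejected(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = True
        for fn in (cn.clustering_coefficient, cn.local_efficiency,
                   cn.nodal_path_length, cn.betweenness):
            with pytest.raises(ValueError):
                fn(a)


class TestOracleEquivalence:
    """All five nodal measures match brute-force enumeration exactly on
    random small graphs (dense and compiled code paths)."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            n = int(rng.integers(4, 13))
            adj = random_adjacency(rng, n, float(rng.uniform(0.15, 0.7)))
            assert np.array_equal(cn.degree(adj),
                                  adj.sum(axis=1).astype(int))
            assert np.allclose(cn.clustering_coefficient(adj),
                               bf_clustering(adj), atol=1e-12)
            for method in ("dense", "sparse"):
                assert np.allclose(
                    cn.local_efficiency(adj, method=method),
                    bf_local_efficiency(adj), atol=1e-12)
            L = cn.nodal_path_length(adj)
            Lo = bf_path_length(adj)
            mask = np.isnan(Lo)
            assert np.array_equal(np.isnan(L), mask)
            assert np.allclose(L[~mask], Lo[~mask], atol=1e-12)
            assert np.allclose(cn.betweenness(adj), bf_betweenness(adj),
                               atol=1e-9)

    def test_against_networkx(self):
        """Independent library oracle on a larger graph."""
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(3)
        adj = random_adjacency(rng, 40, 0.15)
        g = nx.from_numpy_array(adj.astype(int))
        bc = cn.betweenness(adj)
        nx_bc = nx.betweenness_centrality(g, normalized=False)
        assert np.allclose(bc, [nx_bc[i] for i in range(40)], atol=1e-9)
        cc = cn.clustering_coefficient(adj)
        nx_cc = nx.clustering(g)
        assert np.allclose(cc, [nx_cc[i] for i in range(40)], atol=1e-12)


class TestMeasureInvariants:
    def test_bounds_and_edge_monotonicity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 12))
            adj = random_adjacency(rng, n, 0.3)
            c = cn.clustering_coefficient(adj)
            le = cn.local_efficiency(adj)
            assert (c >= 0).all() and (c <= 1).all()
            assert (le >= 0).all() and (le <= 1).all()
            # add one absent edge: degree and E_glob never decrease
            absent = np.argwhere(~adj & ~np.eye(n, dtype=bool))
            if len(absent) == 0:
                continue
            i, j = absent[rng.integers(len(absent))]
            adj2 = adj.copy()
            adj2[i, j] = adj2[j, i] = True
            assert (cn.degree(adj2) >= cn.degree(adj)).all()
            e1 = cn._binary_global_efficiency(adj)
            e2 = cn._binary_global_efficiency(adj2)
            assert e2 >= e1 - 1e-12


class TestInterhemispheric:
    def test_lookup(self):
        labels = ["L_V1", "L_MT", "R_V1", "R_MT"]
        w = np.zeros((4, 4))
        w[0, 2] = w[2, 0] = 0.7  # L_V1 <-> R_V1
        w[1, 3] = w[3, 1] = -0.2
        vals = cn.interhemispheric(w, labels)
        assert vals["V1"] == pytest.approx(0.7)
        assert vals["MT"] == pytest.approx(-0.2)

    def test_zero_off_diagonal(self):
        labels = ["L_A", "L_B", "R_A", "R_B"]
        vals = cn.interhemispheric(np.eye(4), labels)
        assert (vals == 0).all()

    def test_unpaired_label_errors(self):
        with pytest.raises(ValueError, match="unpaired"):
            cn.interhemispheric(np.zeros((3, 3)), ["L_A", "L_B", "R_A"])
        with pytest.raises(ValueError, match="prefix"):
            cn.interhemispheric(np.zeros((2, 2)), ["A", "R_A"])
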
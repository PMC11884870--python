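"""Sparse multi-set CCA: operators, ascent, oracles, penalty selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gamebrain import smcca
from gamebrain.smcca import (
    SparseMCCA,
    constrained_update,
    select_penalties,
    soft_threshold,
    _block_matrix,
    _coordinate_ascent,
    _cross_products,
)


class TestSoftThreshold:
    def test_basic_cases(self):
        assert np.allclose(soft_threshold(np.array([3.0, -3.0]), 1.0), [2, -2])
        assert np.allclose(soft_threshold(np.array([0.5]), 1.0), [0.0])
        a = np.array([1.5, -0.2, 0.0])
        assert np.allclose(soft_threshold(a, 0.0), a)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=20),
           st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_shrinks_toward_zero(self, vals, delta):
        a = np.array(vals)
        out = soft_threshold(a, delta)
        assert (np.abs(out) <= np.abs(a) + 1e-12).all()
        assert np.array_equal(np.sign(out[out != 0]), np.sign(a[out != 0]))


class TestConstrainedUpdate:
    def test_loose_bound_just_normalizes(self):
        w, delta, slack = constrained_update(np.array([3.0, 1.0]), np.sqrt(2))
        assert np.allclose(w, np.array([3, 1]) / np.sqrt(10))
        assert delta == 0.0 and slack == 0.0

    def test_tight_bound_selects_single_coordinate(self):
        w, _, slack = constrained_update(np.array([3.0, 1.0]), 1.0)
        assert np.allclose(w, [1.0, 0.0])
        assert slack == 0.0

    def test_tied_entries_report_slack(self):
        w, _, slack = constrained_update(np.array([1.0, 1.0]), 1.0)
        assert np.allclose(w, [np.sqrt(2) / 2, np.sqrt(2) / 2])
        assert slack == pytest.approx(np.sqrt(2) - 1)

    def test_errors(self):
        with pytest.raises(ValueError):
            constrained_update(np.zeros(3), 1.0)
        with pytest.raises(ValueError):
            constrained_update(np.array([1.0, 2.0]), 0.5)  # c < 1
        with pytest.raises(ValueError):
            constrained_update(np.array([1.0, 2.0]), 3.0)  # c > sqrt(p)

    @given(st.integers(2, 40), st.floats(0.05, 1.0), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_delta_grid_scan(self, p, frac, seed):
        """The closed-form smallest delta agrees with a brute-force grid
        scan over delta values."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=p)
        if not np.any(a):
            return
        c = 1.0 + frac * (np.sqrt(p) - 1.0)
        w, delta, slack = constrained_update(a, c)
        assert abs(np.linalg.norm(w) - 1.0) < 1e-9
        assert np.abs(w).sum() <= c + slack + 1e-6
        # grid scan: no feasible delta smaller than the returned one (up to
        # grid resolution) achieves the bound
        for d in np.linspace(0, max(delta - 1e-3, 0), 40):
            su = soft_threshold(a, d)
            nrm = np.linalg.norm(su)
            if nrm == 0:
                continue
            if np.abs(su / nrm).sum() <= c - 1e-9:
                assert d >= delta - 1e-6, (d, delta)


def _random_sets(rng, n, ps, shared=0.0):
    z = rng.normal(size=n)
    sets = {}
    for i, p in enumerate(ps):
        X = rng.normal(size=(n, p))
        if shared > 0:
            X[:, 0] += shared * z
        sets[f"set{i}"] = X
    return sets


class TestFit:
    def test_identical_one_column_sets_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 1))
        res = SparseMCCA({"a": x, "b": x.copy()}, penalty_fractions=1.0).fit()
        assert res.sum_cor == pytest.approx(1.0)

    def test_three_identical_sets_sum_cor_three(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        res = SparseMCCA({"a": X, "b": X.copy(), "c": X.copy()},
                         penalty_fractions=1.0).fit()
        assert res.sum_cor == pytest.approx(3.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_k2_loose_penalty_matches_svd_oracle(self, seed):
        """With two sets and maximal penalties the solution is the rank-1
        SVD of X1'X2 (penalized matrix decomposition oracle)."""
        rng = np.random.default_rng(seed)
        n, p1, p2 = 60, 8, 6
        sets = _random_sets(rng, n, (p1, p2), shared=1.0)
        model = SparseMCCA(sets, penalty_fractions=1.0)
        res = model.fit()
        C = model.Zs[0].T @ model.Zs[1]
        U, _, Vt = np.linalg.svd(C)
        cos1 = abs(res.weights[0].to_numpy() @ U[:, 0])
        cos2 = abs(res.weights[1].to_numpy() @ Vt[0])
        assert cos1 >= 0.99 and cos2 >= 0.99

    def test_objective_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sets = _random_sets(rng, 50, (10, 8, 12), shared=0.5)
            res = SparseMCCA(sets, penalty_fractions=0.4).fit()
            tr = np.array(res.objective_trace)
            assert (np.diff(tr) >= -1e-8 * np.maximum(1, np.abs(tr[:-1]))).all()

    def test_kernel_agrees_with_reference_ascent(self):
        """The compiled ascent and the pure-python reference land on the
        same weights from the same start."""
        rng = np.random.default_rng(4)
        sets = _random_sets(rng, 40, (6, 9, 7), shared=0.8)
        model = SparseMCCA(sets, penalty_fractions=0.6)
        res = model.fit()
        Cfull, offs = _block_matrix(model.Zs)
        w0 = model._initial_weights(model.Zs, Cfull, offs)
        winit = [w0[offs[i]:offs[i + 1]] for i in range(3)]
        C = _cross_products(model.Zs)
        ws, _, _ = _coordinate_ascent(C, winit, model.penalties(), 200, 1e-6)
        got = np.concatenate([w.to_numpy() for w in res.weights])
        assert np.allclose(got, np.concatenate(ws), atol=1e-6)

    def test_identical_joint_permutation_preserves_sum_cor(self):
        rng = np.random.default_rng(5)
        sets = _random_sets(rng, 50, (8, 8), shared=1.0)
        res1 = SparseMCCA(sets, penalty_fractions=0.8).fit()
        perm = rng.permutation(50)
        sets2 = {k: v[perm] for k, v in sets.items()}
        res2 = SparseMCCA(sets2, penalty_fractions=0.8).fit()
        assert res2.sum_cor == pytest.approx(res1.sum_cor, abs=1e-8)

    def test_permuting_one_set_destroys_planted_association(self):
        rng = np.random.default_rng(6)
        sets = _random_sets(rng, 100, (10, 10), shared=3.0)
        res = SparseMCCA(sets, penalty_fractions=0.5).fit()
        drops = []
        for rep in range(10):
            shuffled = dict(sets)
            shuffled["set1"] = sets["set1"][rng.permutation(100)]
            drops.append(SparseMCCA(shuffled, penalty_fractions=0.5)
                         .fit().sum_cor)
        # the null keeps a selection-bias floor but sits far below the
        # planted association
        assert res.sum_cor > 0.8
        assert np.mean(drops) < res.sum_cor - 0.3

    def test_weights_satisfy_constraints(self):
        rng = np.random.default_rng(7)
        sets = _random_sets(rng, 50, (20, 15), shared=1.0)
        model = SparseMCCA(sets, penalty_fractions=0.3)
        res = model.fit()
        for w, c in zip(res.weights, model.penalties()):
            assert np.linalg.norm(w) <= 1 + 1e-8
            assert np.abs(w).sum() <= c + 1e-6

    def test_orient_flips_globally(self):
        rng = np.random.default_rng(8)
        sets = _random_sets(rng, 30, (5, 5), shared=1.0)
        res = SparseMCCA(sets, penalty_fractions=1.0).fit()
        before = res.sum_cor
        v0 = res.variates.iloc[:, 0].copy()
        res.orient(-1)
        assert np.allclose(res.variates.iloc[:, 0], -v0)
        assert res.sum_cor == before  # correlations untouched

    def test_errors(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            SparseMCCA({"only": rng.normal(size=(10, 3))})
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(12, 3))
        with pytest.raises(ValueError):
            SparseMCCA({"a": X, "b": Y})
        Xc = X.copy()
        Xc[:, 0] = 1.0
        with pytest.raises(ValueError, match="constant"):
            SparseMCCA({"a": Xc, "b": X})

    def test_summary_mentions_sets_and_correlation(self):
        rng = np.random.default_rng(10)
        sets = _random_sets(rng, 30, (5, 4), shared=1.0)
        res = SparseMCCA(sets, penalty_fractions=0.8).fit()
        text = res.summary()
        assert "set0" in text and "sum of correlations" in text


class TestSelectPenalties:
    def test_single_grid_point_returned(self):
        rng = np.random.default_rng(0)
        sets = _random_sets(rng, 40, (6, 6), shared=1.0)
        sel = select_penalties(sets, [0.4], n_perm=20, seed=1)
        assert sel.fraction == 0.4
        assert len(sel.table) == 1

    def test_planted_support_recovered(self):
        """With a sparse planted factor the selected penalty keeps weight
        on the planted coordinates (Jaccard >= 0.5)."""
        rng = np.random.default_rng(1)
        n = 217
        z = rng.normal(size=n)
        sets = {}
        support = {}
        for i in range(3):
            p = 20
            X = rng.normal(size=(n, p))
            sup = rng.choice(p, size=4, replace=False)
            X[:, sup] += 1.0 * z[:, None]
            sets[f"s{i}"] = X
            support[f"s{i}"] = set(sup.tolist())
        sel = select_penalties(sets, np.linspace(0.2, 0.8, 4), n_perm=30, seed=2)
        res = SparseMCCA(sets, penalty_fractions=sel.fraction).fit()
        for name, w in zip(res.set_names, res.weights):
            wv = np.abs(w.to_numpy())
            est = set(np.nonzero(wv >= 0.25 * wv.max())[0].tolist())
            jacc = len(est & support[name]) / len(est | support[name])
            assert jacc >= 0.5, (name, jacc)

    def test_errors(self):
        rng = np.random.default_rng(2)
        sets = _random_sets(rng, 20, (4, 4))
        with pytest.raises(ValueError):
            select_penalties(sets, [], n_perm=10)
        with pytest.raises(ValueError):
            select_penalties(sets, [0.5], n_perm=1)
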
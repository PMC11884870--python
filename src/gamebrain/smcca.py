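"""Sparse multi-set canonical correlation analysis (SMCCA).

The model maximizes the sum of pairwise between-set covariances

    sum_{i<j} w_i' X_i' X_j w_j      s.t.  ||w_i||_2 <= 1,  ||w_i||_1 <= c_i

over one sparse weight vector per standardized feature-score set X_i, by
block coordinate ascent: holding the other sets fixed, the update for set i
soft-thresholds a_i = X_i' sum_{j != i} X_j w_j and renormalizes, with the
soft-threshold level chosen (binary search) as the smallest value meeting
the lasso bound. The formulation treats each set's within-set covariance as
the identity (the penalized multi-set convention); classical whitened CCA
is out of scope.

The block-coordinate objective is non-decreasing by construction and is
asserted per iteration. Initialization is deterministic: by default each
w_i starts at the leading left singular direction of its concatenated
cross-covariance blocks [X_i'X_j]_{j != i} (power iteration), which targets
the between-set structure; a per-set within-SVD start is available via
``init='svd'`` but is degenerate on orthogonal score columns.

Penalties are expressed as fractions f of sqrt(p_i): c_i = f * sqrt(p_i),
clipped to [1, sqrt(p_i)]. ``select_penalties`` picks the fraction whose
observed association is most extreme relative to a row-permutation null,
mirroring the permutation-based tuning used with this model family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast

__all__ = [
    "soft_threshold",
    "constrained_update",
    "SparseMCCA",
    "SparseMCCAResults",
    "PenaltySelection",
    "select_penalties",
]


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise sign(a) * max(|a| - delta, 0)."""
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _smallest_delta(x: np.ndarray, c: float) -> float | None:
    """Smallest delta >= 0 such that the normalized soft-thresholded vector
    with magnitudes ``x`` has L1 norm exactly c.

    On the support piece with the m largest magnitudes, the condition
    ||w||_1 = c is a quadratic in delta; the pieces are scanned for the root
    lying inside its bracket. Returns None when the bound is unattainable
    (tied leading magnitudes with sqrt(#ties) > c).
    """
    xs = np.sort(x[x > 0])[::-1]
    p = xs.size
    S1 = np.cumsum(xs)
    S2 = np.cumsum(xs * xs)
    m = np.arange(1, p + 1, dtype=float)
    c2 = c * c
    A = m * (m - c2)
    B = 2.0 * S1 * (c2 - m)
    C = S1 * S1 - c2 * S2
    hi = xs  # exclusive upper bracket for support m
    lo = np.concatenate([xs[1:], [0.0]])  # inclusive lower bracket
    best = None
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = B * B - 4.0 * A * C
        sq = np.sqrt(np.maximum(disc, 0.0))
        quad = np.abs(A) > 1e-12
        root_sets = [
            np.where(quad & (disc >= -1e-12), (-B - sq) / (2.0 * A), np.nan),
            np.where(quad & (disc >= -1e-12), (-B + sq) / (2.0 * A), np.nan),
            # degenerate (m == c^2) piece is linear in delta
            np.where(~quad & (np.abs(B) > 1e-12),
                     -C / np.where(B == 0, 1.0, B), np.nan),
            # identically satisfied piece: every delta works, take its floor
            np.where(~quad & (np.abs(B) <= 1e-12)
                     & (np.abs(C) <= 1e-9 * (S1 * S1 + 1.0)),
                     np.maximum(lo, 0.0), np.nan),
        ]
    for roots in root_sets:
        valid = (np.isfinite(roots) & (roots >= 0.0)
                 & (roots >= lo - 1e-12) & (roots < hi))
        if valid.any():
            d = float(roots[valid].min())
            best = d if best is None else min(best, d)
    return best


def constrained_update(a: np.ndarray, c: float) -> tuple[np.ndarray, float, float]:
    """Unit-norm soft-thresholded update with L1 bound c.

    Returns ``(w, delta, slack)`` where w = S(a, delta)/||S(a, delta)||_2
    with the smallest delta >= 0 such that ||w||_1 <= c (solved exactly on
    the sorted-support pieces of the soft-threshold path). When the bound is
    unattainable for the sign pattern (tied leading entries whose normalized
    L1 norm exceeds c), the nearest-feasible w (the tied set, equally
    weighted) is returned and the remaining slack ||w||_1 - c is reported.
    """
    a = np.asarray(a, dtype=float)
    if not np.any(a):
        raise ValueError("zero vector has no direction")
    if not (1.0 <= c <= np.sqrt(a.size) + 1e-12):
        raise ValueError(f"lasso bound c={c} outside [1, sqrt(p)]")

    x = np.abs(a)
    su = soft_threshold(a, 0.0)
    w0 = su / np.linalg.norm(su)
    if np.abs(w0).sum() <= c + 1e-12:
        return w0, 0.0, 0.0

    delta = _smallest_delta(x, c)
    if delta is None:
        # unattainable: collapse to the tied maximal entries
        tied = x >= x.max() - 1e-12 * max(x.max(), 1.0)
        su = np.sign(a) * tied
        w = su / np.linalg.norm(su)
        return w, float(x.max()), max(0.0, float(np.abs(w).sum()) - c)
    su = soft_threshold(a, delta)
    nrm = np.linalg.norm(su)
    if nrm == 0:  # numerical corner: fall back to the tied set
        tied = x >= x.max() - 1e-12 * max(x.max(), 1.0)
        su = np.sign(a) * tied
        nrm = np.linalg.norm(su)
    w = su / nrm
    slack = max(0.0, float(np.abs(w).sum()) - c)
    return w, float(delta), slack if slack > 1e-9 else 0.0


# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant columns cannot enter the SMCCA")
    return (X - mu) / sd


def _fix_sign(v: np.ndarray) -> np.ndarray:
    j = np.argmax(np.abs(v))
    return v if v[j] >= 0 else -v


def _leading_right_singular(X: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return _fix_sign(vt[0])


def _cross_products(Zs: list[np.ndarray]) -> dict[tuple[int, int], np.ndarray]:
    K = len(Zs)
    return {(i, j): Zs[i].T @ Zs[j] for i in range(K) for j in range(i + 1, K)}


def _block_matrix(Zs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stacked symmetric cross-product matrix with zero diagonal blocks,
    plus the block offsets."""
    ps = [Z.shape[1] for Z in Zs]
    offs = np.concatenate([[0], np.cumsum(ps)]).astype(np.int64)
    P = int(offs[-1])
    Cfull = np.zeros((P, P))
    for i in range(len(Zs)):
        for j in range(i + 1, len(Zs)):
            B = Zs[i].T @ Zs[j]
            Cfull[offs[i]:offs[i + 1], offs[j]:offs[j + 1]] = B
            Cfull[offs[j]:offs[j + 1], offs[i]:offs[i + 1]] = B.T
    return Cfull, offs


def _coordinate_ascent(
    C: dict[tuple[int, int], np.ndarray],
    winit: list[np.ndarray],
    cs: list[float],
    max_iter: int,
    tol: float,
) -> tuple[list[np.ndarray], list[float], bool]:
    """Pure-python reference of the block coordinate ascent (the compiled
    kernel is the production path; tests assert their equivalence)."""
    K = len(winit)
    # bring initial directions into the feasible set (unit L2, L1 <= c)
    ws = []
    for w, c in zip(winit, cs):
        if np.any(w) and np.abs(w).sum() > c:
            w, _, _ = constrained_update(w, c)
        ws.append(w.copy())

    def cij(i: int, j: int) -> np.ndarray:
        return C[(i, j)] if i < j else C[(j, i)].T

    def objective() -> float:
        return float(sum(ws[i] @ cij(i, j) @ ws[j]
                         for i in range(K) for j in range(i + 1, K)))

    trace = [objective()]
    converged = False
    for _ in range(max_iter):
        for i in range(K):
            a = np.zeros_like(ws[i])
            for j in range(K):
                if j != i:
                    a += cij(i, j) @ ws[j]
            if np.any(a):
                ws[i], _, _ = constrained_update(a, cs[i])
        obj = objective()
        if obj < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise RuntimeError("objective decreased — numerical failure in ascent")
        denom = max(abs(trace[-1]), 1e-12)
        done = abs(obj - trace[-1]) / denom < tol
        trace.append(obj)
        if done:
            converged = True
            break
    return ws, trace, converged


@dataclass
class SparseMCCAResults:
    """Fitted SMCCA: per-set sparse weights, canonical variates and the sum
    of pairwise canonical correlations, with the optimization trace."""

    set_names: list[str]
    weights: list[pd.Series]
    penalties: list[float]
    penalty_fractions: list[float] | None
    variates: pd.DataFrame  # participants x sets
    pairwise_correlations: pd.DataFrame
    sum_cor: float
    objective_trace: list[float]
    converged: bool
    n_components: int = 1
    extra_components: list["SparseMCCAResults"] = field(default_factory=list)

    def orient(self, sign: int) -> None:
        """Globally flip every set's weights and variates (sign convention
        only; all pairwise correlations are unchanged)."""
        if sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if sign == -1:
            self.weights = [-w for w in self.weights]
            self.variates = -self.variates

    def summary(self) -> str:
        lines = [
            "Sparse multi-set CCA results",
            "=" * 60,
            f"{'set':<28}{'p':>6}{'c (L1)':>10}{'nnz(w)':>8}",
        ]
        for name, w, c in zip(self.set_names, self.weights, self.penalties):
            nnz = int((w.abs() > 1e-10).sum())
            lines.append(f"{name:<28}{len(w):>6}{c:>10.3f}{nnz:>8}")
        lines.append("-" * 60)
        lines.append("pairwise canonical correlations:")
        for i, a in enumerate(self.set_names):
            for j in range(i + 1, len(self.set_names)):
                r = self.pairwise_correlations.iloc[i, j]
                lines.append(f"  cor({a}, {self.set_names[j]}) = {r:+.3f}")
        lines.append(f"sum of correlations: {self.sum_cor:.3f}")
        lines.append(f"converged: {self.converged} "
                     f"({len(self.objective_trace) - 1} iterations)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "set_names": self.set_names,
            "weights": {n: w.to_dict() for n, w in zip(self.set_names, self.weights)},
            "penalties": self.penalties,
            "penalty_fractions": self.penalty_fractions,
            "pairwise_correlations": self.pairwise_correlations.to_dict(),
            "sum_cor": self.sum_cor,
            "objective_trace": self.objective_trace,
            "converged": self.converged,
        }


class SparseMCCA:
    """Sparse multi-set CCA model over K feature-score sets.

    Parameters
    ----------
    sets : dict of name -> (participants x features) DataFrame/array
        All sets must share the participant index. Columns are standardized
        internally.
    penalty_fractions : float or sequence, optional
        Per-set lasso bounds as fractions of sqrt(p_i); a scalar is shared
        by all sets. Defaults to 0.5.
    """

    def __init__(
        self,
        sets: dict[str, pd.DataFrame | np.ndarray],
        penalty_fractions: float | list[float] | None = None,
        *,
        n_components: int = 1,
        max_iter: int = 200,
        tol: float = 1e-6,
        init: str = "cross",
    ) -> None:
        if len(sets) < 2:
            raise ValueError("need at least two sets")
        self.set_names = list(sets.keys())
        self.index = None
        Zs, cols = [], []
        n = None
        for name, X in sets.items():
            if isinstance(X, pd.DataFrame):
                if self.index is None:
                    self.index = X.index
                elif not X.index.equals(self.index):
                    raise ValueError("all sets must share the participant index")
                cols.append(list(X.columns))
                X = X.to_numpy(float)
            else:
                X = np.asarray(X, dtype=float)
                cols.append(list(range(X.shape[1])))
            if n is None:
                n = X.shape[0]
            elif X.shape[0] != n:
                raise ValueError("sets have different numbers of participants")
            Zs.append(_standardize(X))
        if self.index is None:
            self.index = pd.RangeIndex(n)
        self.Zs = Zs
        self.columns = cols
        self.n = n
        if penalty_fractions is None:
            penalty_fractions = 0.5
        if np.isscalar(penalty_fractions):
            penalty_fractions = [float(penalty_fractions)] * len(Zs)
        self.penalty_fractions = [float(f) for f in penalty_fractions]
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        if init not in ("cross", "svd"):
            raise ValueError("init must be 'cross' or 'svd'")
        self.init = init

    def penalties(self) -> list[float]:
        return [
            float(np.clip(f * np.sqrt(Z.shape[1]), 1.0, np.sqrt(Z.shape[1])))
            for f, Z in zip(self.penalty_fractions, self.Zs)
        ]

    def _initial_weights(self, Zs: list[np.ndarray], Cfull: np.ndarray,
                         offs: np.ndarray) -> np.ndarray:
        if self.init == "svd":
            return np.concatenate([_leading_right_singular(Z) for Z in Zs])
        K = len(Zs)
        ws = []
        for i in range(K):
            M = Cfull[offs[i]:offs[i + 1], :]
            p = M.shape[0]
            u = np.ones(p) / np.sqrt(p)
            for _ in range(12):
                v = M.T @ u
                nv = np.linalg.norm(v)
                if nv == 0:
                    break
                u = M @ (v / nv)
                nu = np.linalg.norm(u)
                if nu == 0:
                    u = np.ones(p) / np.sqrt(p)
                    break
                u = u / nu
            ws.append(_fix_sign(u))
        return np.concatenate(ws)

    def _ascend(self, Zs: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray, bool]:
        cs = np.asarray(self.penalties())
        Cfull, offs = _block_matrix(Zs)
        w0 = self._initial_weights(Zs, Cfull, offs)
        w, trace, n_iter, converged, monotone = _fast.smcca_ascent(
            Cfull, offs, cs, w0, self.max_iter, self.tol)
        if not monotone:
            raise RuntimeError("objective decreased — numerical failure in ascent")
        ws = [w[offs[i]:offs[i + 1]] for i in range(len(Zs))]
        return ws, trace, converged

    def _fit_once(self, Zs: list[np.ndarray]) -> SparseMCCAResults:
        cs = self.penalties()
        ws, trace, converged = self._ascend(Zs)
        us = np.column_stack([Z @ w for Z, w in zip(Zs, ws)])
        R = np.corrcoef(us, rowvar=False)
        K = len(Zs)
        sum_cor = float(sum(R[i, j] for i in range(K) for j in range(i + 1, K)))
        return SparseMCCAResults(
            set_names=self.set_names,
            weights=[pd.Series(w, index=c) for w, c in zip(ws, self.columns)],
            penalties=cs,
            penalty_fractions=self.penalty_fractions,
            variates=pd.DataFrame(us, index=self.index, columns=self.set_names),
            pairwise_correlations=pd.DataFrame(R, index=self.set_names,
                                               columns=self.set_names),
            sum_cor=sum_cor,
            objective_trace=[float(v) for v in trace],
            converged=converged,
        )

    def fit(self) -> SparseMCCAResults:
        res = self._fit_once(self.Zs)
        if self.n_components > 1:
            Zs = [Z.copy() for Z in self.Zs]
            prev = res
            for _ in range(1, self.n_components):
                # deflate each set on its own earlier variate, then refit
                Zs = [
                    Z - np.outer(u, u @ Z) / float(u @ u)
                    for Z, u in zip(Zs, prev.variates.to_numpy().T)
                ]
                prev = self._fit_once(Zs)
                res.extra_components.append(prev)
            res.n_components = self.n_components
        return res

    # -- internal: fast refit on permuted rows (fixed penalties)
    def _fit_permuted(self, perms: list[np.ndarray | None]) -> float:
        Zs = [Z if p is None else Z[p] for Z, p in zip(self.Zs, perms)]
        ws, _, _ = self._ascend(Zs)
        us = np.column_stack([Z @ w for Z, w in zip(Zs, ws)])
        sd = us.std(axis=0)
        if np.any(sd == 0):
            return 0.0
        R = np.corrcoef(us, rowvar=False)
        K = len(Zs)
        return float(sum(R[i, j] for i in range(K) for j in range(i + 1, K)))


@dataclass
class PenaltySelection:
    fraction: float
    penalties: list[float]
    zstat: float
    table: pd.DataFrame  # per grid point: fraction, sum_cor, z_obs, mean/sd of null z

    def summary(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:8.4f}")


def _fisher_mean_z(sum_cor: float, n_pairs: int) -> float:
    r = np.clip(sum_cor / n_pairs, -0.999999, 0.999999)
    return float(np.arctanh(r))


def select_penalties(
    sets: dict[str, pd.DataFrame | np.ndarray],
    penalty_grid: list[float] | np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    **model_kw,
) -> PenaltySelection:
    """Permutation-based selection of the shared penalty fraction.

    For every grid fraction the observed sum of canonical correlations is
    compared, on the Fisher-z scale of the mean pairwise correlation, with
    the distribution obtained by independently row-permuting each set
    (``n_perm`` replicates, the same permutations reused across the grid).
    The fraction maximizing (z_obs - mean z_perm) / sd z_perm is selected.
    """
    if penalty_grid is None:
        penalty_grid = np.linspace(0.1, 0.9, 10)
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0:
        raise ValueError("empty penalty grid")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    rng = np.random.default_rng(seed)
    model0 = SparseMCCA(sets, penalty_fractions=float(penalty_grid[0]), **model_kw)
    K = len(model0.Zs)
    n_pairs = K * (K - 1) // 2
    perms = [[rng.permutation(model0.n) for _ in range(K)] for _ in range(n_perm)]

    rows = []
    for f in penalty_grid:
        model0.penalty_fractions = [float(f)] * K
        obs = model0._fit_once(model0.Zs).sum_cor
        z_obs = _fisher_mean_z(obs, n_pairs)
        z_perm = np.array([
            _fisher_mean_z(model0._fit_permuted(p), n_pairs) for p in perms
        ])
        sd = z_perm.std(ddof=1)
        z = (z_obs - z_perm.mean()) / sd if sd > 0 else 0.0
        rows.append((float(f), obs, z_obs, z_perm.mean(), sd, float(z)))
    table = pd.DataFrame(
        rows, columns=["fraction", "sum_cor", "z_obs", "z_perm_mean",
                       "z_perm_sd", "zstat"],
    )
    best = int(table["zstat"].idxmax())
    frac = float(table.loc[best, "fraction"])
    model0.penalty_fractions = [frac] * K
    return PenaltySelection(
        fraction=frac, penalties=model0.penalties(),
        zstat=float(table.loc[best, "zstat"]), table=table,
    )
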
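"""Connectome construction and graph-theoretic nodal measures.

Edges of the functional network are Pearson correlations between regional
time series; structural networks are waytotal-normalized streamline counts,
symmetrized as (M + M.T)/2. Each weighted network is binarized at the
threshold that maximizes global cost efficiency (global efficiency minus
network cost), and five nodal measures are computed on the binary graph:
clustering coefficient and local efficiency (segregation), nodal path
length (integration), degree and betweenness centrality (centrality).
Homotopic interhemispheric connectivity — the edge between the same parcel
in the two hemispheres — is read off the weighted (pre-threshold) matrix.

Shortest paths, betweenness (Brandes) and local efficiency run on compiled
BFS kernels for large networks; clustering is vectorized numpy. Only
binarization topology matters, so the cost-efficiency search is invariant
to monotone transformations of the edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from . import _fast

__all__ = [
    "correlation_matrix",
    "normalize_tractography",
    "threshold_cost_efficiency",
    "ThresholdResult",
    "clustering_coefficient",
    "local_efficiency",
    "nodal_path_length",
    "betweenness",
    "degree",
    "NodalMetrics",
    "nodal_metrics",
    "interhemispheric",
    "split_hemispheres",
]


def correlation_matrix(time_series: np.ndarray) -> np.ndarray:
    """Pearson correlation of node time series (time x nodes) -> nodes x nodes."""
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a time x nodes array with at least 3 time points")
    if np.isnan(ts).any():
        raise ValueError("time series contain NaNs")
    if np.any(ts.std(axis=0) == 0):
        raise ValueError("constant node series")
    r = np.corrcoef(ts, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def normalize_tractography(counts: np.ndarray, waytotal: np.ndarray) -> np.ndarray:
    """Divide each row of the streamline-count matrix by its waytotal, then
    symmetrize as (M + M.T)/2 for graph analysis."""
    counts = np.asarray(counts, dtype=float)
    waytotal = np.asarray(waytotal, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative streamline counts")
    if np.any(waytotal <= 0):
        raise ValueError("waytotal must be positive for every row")
    m = counts / waytotal[:, None]
    return 0.5 * (m + m.T)


# ---------------------------------------------------------------------------
# Cost-efficiency thresholding
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    adjacency: np.ndarray  # boolean nodes x nodes
    threshold: float
    cost: float
    global_efficiency: float
    cost_efficiency: float


def _binary_global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d over ordered node pairs on a binary graph (1/inf = 0)."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def threshold_cost_efficiency(
    matrix: np.ndarray,
    *,
    max_candidates: int = 60,
    use_absolute: bool = True,
    n_sources: int | None = None,
    cost_range: tuple[float, float] = (0.01, 0.45),
) -> ThresholdResult:
    """Pick the binarization threshold maximizing global cost efficiency.

    Candidate thresholds are the sorted unique absolute edge weights
    (equivalently a sweep over network cost); when there are more unique
    weights than ``max_candidates`` the sweep is taken over an evenly spaced
    grid of network costs within ``cost_range``, which preserves invariance
    to monotone weight transformations. Binarization keeps edges with
    ``|w| >= t`` (``w >= t`` when ``use_absolute=False``), so every
    candidate threshold retains at least one edge. CE = E_glob - cost; ties
    break toward lower cost. On large networks ``n_sources`` evenly strided
    BFS sources may be used to estimate E_glob during the sweep (the
    reported optimum is re-expressed exactly downstream).
    """
    w = np.asarray(matrix, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    n = w.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if not np.allclose(w, w.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    strengths = np.abs(w) if use_absolute else w.copy()
    np.fill_diagonal(strengths, 0.0)
    iu = np.triu_indices(n, k=1)
    upper = strengths[iu]
    positive = upper[upper > 0]
    if positive.size == 0:
        raise ValueError("matrix has no nonzero edges")

    n_pairs = n * (n - 1) / 2.0
    uniq = np.unique(positive)
    sources = np.arange(n)
    if n_sources is not None and n_sources < n:
        sources = np.unique(np.linspace(0, n - 1, n_sources).round().astype(int))

    exhaustive = uniq.size <= max_candidates
    if exhaustive and n <= 64:
        best = None  # (ce, cost, eg, t)
        for t in uniq[::-1]:  # descending: increasing cost
            adj = strengths >= t
            np.fill_diagonal(adj, False)
            cost = float(adj[iu].sum() / n_pairs)
            eg = _binary_global_efficiency(adj)
            ce = eg - cost
            if best is None or ce > best[0] + 1e-12 or (
                abs(ce - best[0]) <= 1e-12 and cost < best[1]
            ):
                best = (ce, cost, eg, float(t))
        assert best is not None
        ce, cost, eg, t = best
    else:
        order = np.argsort(upper, kind="stable")[::-1]
        sorted_w = upper[order]
        if exhaustive:
            thresholds = uniq[::-1]
        else:
            lo = max(1, int(round(cost_range[0] * n_pairs)))
            hi = min(int(np.count_nonzero(positive)),
                     int(round(cost_range[1] * n_pairs)))
            kgrid = np.unique(np.linspace(lo, max(lo, hi), max_candidates)
                              .round().astype(int))
            thresholds = np.unique(sorted_w[kgrid - 1])[::-1]
        # tie-aware edge counts: k(t) = #{edges with strength >= t}
        ks = np.searchsorted(-sorted_w, -thresholds, side="right").astype(np.int64)
        egs = _fast.ce_sweep(
            iu[0][order].astype(np.int64), iu[1][order].astype(np.int64),
            ks, sources.astype(np.int64), n)
        costs = ks / n_pairs
        ces = egs - costs
        # argmax with ties broken toward lower cost
        best_i = 0
        for i in range(1, len(ces)):
            if ces[i] > ces[best_i] + 1e-12 or (
                abs(ces[i] - ces[best_i]) <= 1e-12 and costs[i] < costs[best_i]
            ):
                best_i = i
        ce, cost, eg, t = (float(ces[best_i]), float(costs[best_i]),
                           float(egs[best_i]), float(thresholds[best_i]))
    adj = strengths >= t
    np.fill_diagonal(adj, False)
    return ThresholdResult(adj, t, cost, eg, ce)


# ---------------------------------------------------------------------------
# Nodal measures (binary symmetric adjacency)
# ---------------------------------------------------------------------------

def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = a.astype(bool)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, False)
    return a


def degree(adj: np.ndarray, node: int | None = None):
    a = _check_adjacency(adj)
    k = a.sum(axis=1).astype(int)
    return k if node is None else int(k[node])


def clustering_coefficient(adj: np.ndarray, node: int | None = None):
    """C_i = 2 t_i / [k_i (k_i - 1)], triangles t_i through node i; 0 if k<2."""
    a = _check_adjacency(adj)
    af = a.astype(float)
    t = ((af @ af) * af).sum(axis=1) / 2.0
    k = af.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = 2.0 * t / (k * (k - 1.0))
    c[k < 2] = 0.0
    return c if node is None else float(c[node])


def _subgraph_distances(sub: np.ndarray) -> np.ndarray:
    """All-pairs hop distances on a small boolean adjacency via boolean
    matrix expansion (inf where unreachable)."""
    m = sub.shape[0]
    subf = sub.astype(np.float32)
    dist = np.full((m, m), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[sub] = 1.0
    reach = sub | np.eye(m, dtype=bool)
    # distance sets are downward closed (vertices on a shortest path realize
    # every smaller distance), so an empty level means only inf remains
    P = subf
    d = 2
    while d <= m:
        P = ((P @ subf) > 0).astype(np.float32)
        new = (P > 0) & ~reach
        if not new.any():
            break
        dist[new] = d
        reach |= new
        d += 1
    return dist


def local_efficiency(adj: np.ndarray, node: int | None = None, *,
                     method: str = "auto"):
    """Efficiency of the subgraph induced by each node's neighbors: mean of
    1/d over neighbor pairs (within-subgraph distances); 0 if k < 2.

    ``method``: 'dense' (numpy level-set expansion), 'sparse' (compiled
    BFS over all nodes), or 'auto' (sparse for networks above 64 nodes).
    """
    a = _check_adjacency(adj)
    if method not in ("auto", "dense", "sparse"):
        raise ValueError("method must be auto, dense or sparse")
    if method == "sparse" or (method == "auto" and a.shape[0] > 64 and node is None):
        A = csr_matrix(a)
        out = _fast.local_efficiency_all(A.indptr, A.indices, a.shape[0])
        return out if node is None else float(out[node])
    nodes = range(a.shape[0]) if node is None else [node]
    out = np.zeros(a.shape[0])
    for i in nodes:
        nb = np.nonzero(a[i])[0]
        k = nb.size
        if k < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        d = _subgraph_distances(sub)
        iu = np.triu_indices(k, 1)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d[iu]
        inv[~np.isfinite(inv)] = 0.0
        out[i] = float(inv.mean())
    return out if node is None else float(out[node])


def nodal_path_length(adj: np.ndarray, node: int | None = None, *, return_flags: bool = False):
    """Mean shortest-path hop distance to all *reachable* nodes.

    Unreachable targets are excluded; a node with no reachable targets gets
    NaN. With ``return_flags=True`` also returns a boolean vector marking
    nodes for which some target was unreachable (or the node was isolated).
    """
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n > 64:
        d = np.asarray(_to_igraph(a).distances(), dtype=float)
    else:
        d = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        L = sums / counts
    L[counts == 0] = np.nan
    flags = counts < (n - 1)
    if node is not None:
        return (float(L[node]), bool(flags[node])) if return_flags else float(L[node])
    return (L, flags) if return_flags else L


def betweenness(adj: np.ndarray, node: int | None = None):
    """Unnormalized betweenness centrality: sum over unordered pairs (s, t),
    s != t != i, of the fraction of shortest s-t paths through i."""
    a = _check_adjacency(adj)
    A = csr_matrix(a)
    b = _fast.betweenness_all(A.indptr, A.indices, a.shape[0])
    return b if node is None else float(b[node])


@dataclass
class NodalMetrics:
    clustering: np.ndarray
    local_efficiency: np.ndarray
    path_length: np.ndarray
    degree: np.ndarray
    betweenness: np.ndarray
    path_length_flags: np.ndarray
    threshold: float
    cost: float
    global_efficiency: float

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "clustering": self.clustering,
                "local_efficiency": self.local_efficiency,
                "path_length": self.path_length,
                "degree": self.degree,
                "betweenness": self.betweenness,
            }
        )
        if labels is not None:
            df.index = pd.Index(labels, name="region")
        return df


def nodal_metrics(matrix: np.ndarray, *, use_absolute: bool = True,
                  max_candidates: int = 60,
                  n_sources: int | None = None) -> NodalMetrics:
    """Threshold a weighted matrix by maximal cost efficiency and compute the
    five nodal measures on the resulting binary graph."""
    thr = threshold_cost_efficiency(matrix, use_absolute=use_absolute,
                                    max_candidates=max_candidates,
                                    n_sources=n_sources)
    adj = thr.adjacency
    n = adj.shape[0]
    A = csr_matrix(adj)
    sums, counts = _fast.path_length_stats(A.indptr, A.indices, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        L = sums / counts
    L[counts == 0] = np.nan
    flags = counts < (n - 1)
    return NodalMetrics(
        clustering=clustering_coefficient(adj),
        local_efficiency=local_efficiency(adj),
        path_length=L,
        degree=adj.sum(axis=1).astype(float),
        betweenness=_fast.betweenness_all(A.indptr, A.indices, n),
        path_length_flags=flags,
        threshold=thr.threshold,
        cost=thr.cost,
        global_efficiency=thr.global_efficiency,
    )


# ---------------------------------------------------------------------------
# Homotopic interhemispheric connectivity
# ---------------------------------------------------------------------------

def split_hemispheres(labels: list[str]) -> tuple[dict[str, int], dict[str, int]]:
    left, right = {}, {}
    for i, lb in enumerate(labels):
        if lb.startswith("L_"):
            left[lb[2:]] = i
        elif lb.startswith("R_"):
            right[lb[2:]] = i
        else:
            raise ValueError(f"label {lb!r} has no L_/R_ hemisphere prefix")
    return left, right


def interhemispheric(matrix: np.ndarray, labels: list[str]) -> pd.Series:
    """Weighted connectivity between the same parcel in the two hemispheres,
    one value per homotopic pair, taken from the pre-threshold matrix."""
    w = np.asarray(matrix, dtype=float)
    left, right = split_hemispheres(labels)
    if set(left) != set(right):
        unpaired = set(left) ^ set(right)
        raise ValueError(f"unpaired parcels: {sorted(unpaired)[:5]}")
    parcels = [lb[2:] for lb in labels if lb.startswith("L_")]
    vals = [w[left[p], right[p]] for p in parcels]
    return pd.Series(vals, index=pd.Index(parcels, name="parcel"))
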
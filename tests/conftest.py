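"""Shared fixtures and independent brute-force oracles.

The graph oracles here deliberately avoid the package's own algorithms:
distances come from a plain queue-based BFS, triangle counts from explicit
neighbor-pair enumeration, and shortest-path counts from a recursive
predecessor decomposition, so they can certify the production kernels.
"""

from __future__ import annotations

import numpy as np
import pytest

from gamebrain import synth


# ---------------------------------------------------------------------------
# brute-force graph oracles (small n only)
# ---------------------------------------------------------------------------

def bf_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for s in range(n):
        d[s, s] = 0
        frontier = [s]
        level = 0
        while frontier:
            level += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and not np.isfinite(d[s, v]):
                        d[s, v] = level
                        nxt.append(v)
            frontier = nxt
    return d


def bf_degree(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1).astype(int)


def bf_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        t = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nb[a], nb[b]]
        )
        out[i] = 2.0 * t / (k * (k - 1))
    return out


def bf_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        d = bf_distances(sub)
        acc = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                if np.isfinite(d[a, b]) and d[a, b] > 0:
                    acc += 1.0 / d[a, b]
        out[i] = acc / (k * (k - 1) / 2.0)
    return out


def bf_path_length(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = bf_distances(adj)
    out = np.full(n, np.nan)
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if vals:
            out[i] = float(np.mean(vals))
    return out


def _count_shortest_paths(adj: np.ndarray, d: np.ndarray, s: int, t: int) -> int:
    if s == t:
        return 1
    if not np.isfinite(d[s, t]):
        return 0
    return sum(
        _count_shortest_paths(adj, d, s, v)
        for v in range(adj.shape[0])
        if adj[v, t] and d[s, v] == d[s, t] - 1
    )


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = bf_distances(adj)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == i or t == i or not np.isfinite(d[s, t]):
                    continue
                sigma = _count_shortest_paths(adj, d, s, t)
                if sigma == 0:
                    continue
                if d[s, i] + d[i, t] == d[s, t]:
                    through = (_count_shortest_paths(adj, d, s, i)
                               * _count_shortest_paths(adj, d, i, t))
                else:
                    through = 0
                acc += through / sigma
        out[i] = acc
    return out


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    a = rng.random((n, n)) < p
    adj = np.triu(a, 1)
    adj = adj | adj.T
    return adj


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_CFG = synth.SimulationConfig(n_parcels_per_hemi=15, n_modules=3)


@pytest.fixture(scope="session")
def small_study() -> synth.SyntheticStudy:
    """A light study (30 parcels, 50 participants) for module-level tests."""
    return synth.simulate_study(50, seed=42, config=SMALL_CFG)


@pytest.fixture(scope="session")
def null_study() -> synth.SyntheticStudy:
    """Same scale but with every planted effect switched off (snr=0)."""
    cfg = synth.SimulationConfig(n_parcels_per_hemi=15, n_modules=3, snr=0.0)
    return synth.simulate_study(50, seed=43, config=cfg)
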
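"""Compiled BFS kernels for large binary graphs (numba).

These are plain breadth-first searches on CSR adjacency, used where the
pure-numpy implementations would dominate the pipeline runtime: the
cost-efficiency threshold sweep, exact all-pairs nodal path lengths, and
local efficiency. They are checked exactly against brute-force oracles in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["path_length_stats", "local_efficiency_all",
           "ce_sweep", "betweenness_all", "smcca_ascent"]


@njit(cache=True)
def _block_update(a, c, w, lo_idx):  # pragma: no cover - compiled
    """In-place penalized update of one weight block: w[lo_idx:lo_idx+p] =
    S(a, delta)/||S||_2 with the smallest delta >= 0 meeting ||w||_1 <= c
    (exact solve on the sorted-support pieces)."""
    p = a.shape[0]
    l2 = 0.0
    l1 = 0.0
    amax = 0.0
    for j in range(p):
        x = abs(a[j])
        l1 += x
        l2 += x * x
        if x > amax:
            amax = x
    if l2 == 0.0:
        return  # zero direction: keep previous block
    l2 = np.sqrt(l2)
    if l1 / l2 <= c + 1e-12:
        for j in range(p):
            w[lo_idx + j] = a[j] / l2
        return
    xs = np.sort(np.abs(a))[::-1]
    c2 = c * c
    S1 = 0.0
    S2 = 0.0
    best = -1.0
    for m in range(1, p + 1):
        x = xs[m - 1]
        if x <= 0.0:
            break
        S1 += x
        S2 += x * x
        hi = xs[m - 1]
        lo = xs[m] if m < p else 0.0
        A = m * (m - c2)
        B = 2.0 * S1 * (c2 - m)
        C = S1 * S1 - c2 * S2
        if abs(A) > 1e-12:
            disc = B * B - 4.0 * A * C
            if disc >= -1e-12:
                sq = np.sqrt(disc if disc > 0.0 else 0.0)
                for sgn in (-1.0, 1.0):
                    r = (-B + sgn * sq) / (2.0 * A)
                    if r >= 0.0 and r >= lo - 1e-12 and r < hi:
                        if best < 0.0 or r < best:
                            best = r
        elif abs(B) > 1e-12:
            r = -C / B
            if r >= 0.0 and r >= lo - 1e-12 and r < hi:
                if best < 0.0 or r < best:
                    best = r
        elif abs(C) <= 1e-9 * (S1 * S1 + 1.0):
            # identically satisfied on this piece: smallest delta is its floor
            r = lo if lo > 0.0 else 0.0
            if best < 0.0 or r < best:
                best = r
    if best < 0.0:
        # unattainable: tied maximal entries, equally weighted
        tol = 1e-12 * (amax if amax > 1.0 else 1.0)
        cnt = 0
        for j in range(p):
            if abs(a[j]) >= amax - tol:
                cnt += 1
        nrm = np.sqrt(cnt)
        for j in range(p):
            if abs(a[j]) >= amax - tol:
                w[lo_idx + j] = (1.0 if a[j] > 0 else -1.0) / nrm
            else:
                w[lo_idx + j] = 0.0
        return
    nrm = 0.0
    for j in range(p):
        x = abs(a[j]) - best
        if x > 0.0:
            nrm += x * x
    nrm = np.sqrt(nrm)
    if nrm == 0.0:
        return
    for j in range(p):
        x = abs(a[j]) - best
        w[lo_idx + j] = ((1.0 if a[j] > 0 else -1.0) * x / nrm) if x > 0.0 else 0.0


@njit(cache=True)
def smcca_ascent(Cfull, offs, cs, w0, max_iter, tol):  # pragma: no cover - compiled
    """Block coordinate ascent on sum_{i<j} w_i' C_ij w_j.

    ``Cfull`` is the symmetric block cross-product matrix with zero diagonal
    blocks; ``offs`` are block offsets (len K+1); ``w0`` the stacked initial
    weights. Returns (w, trace, n_iter, converged, monotone) where trace[k]
    is the objective after k sweeps (trace[0] = at the projected start).
    """
    K = offs.shape[0] - 1
    P = Cfull.shape[0]
    w = w0.copy()
    # project the start into the feasible set
    for i in range(K):
        p = offs[i + 1] - offs[i]
        blk = w[offs[i]:offs[i + 1]]
        l1 = 0.0
        l2 = 0.0
        for j in range(p):
            l1 += abs(blk[j])
            l2 += blk[j] * blk[j]
        if l2 > 0.0 and l1 / np.sqrt(l2) > cs[i] + 1e-12:
            _block_update(blk.copy(), cs[i], w, offs[i])

    trace = np.empty(max_iter + 1)
    tmp = Cfull @ w
    obj = 0.5 * np.dot(w, tmp)
    trace[0] = obj
    converged = False
    monotone = True
    n_iter = 0
    for it in range(max_iter):
        for i in range(K):
            # Cfull is symmetric with zero diagonal blocks, so the full
            # matvec sliced to block i equals X_i' sum_{j!=i} X_j w_j
            a = (Cfull @ w)[offs[i]:offs[i + 1]].copy()
            nonzero = False
            for j in range(a.shape[0]):
                if a[j] != 0.0:
                    nonzero = True
                    break
            if nonzero:
                _block_update(a, cs[i], w, offs[i])
        new_obj = 0.5 * np.dot(w, Cfull @ w)
        n_iter = it + 1
        trace[n_iter] = new_obj
        if new_obj < obj - 1e-8 * (abs(obj) if abs(obj) > 1.0 else 1.0):
            monotone = False
        denom = abs(obj) if abs(obj) > 1e-12 else 1e-12
        done = abs(new_obj - obj) / denom < tol
        obj = new_obj
        if done:
            converged = True
            break
    return w, trace[:n_iter + 1], n_iter, converged, monotone


@njit(cache=True)
def ce_sweep(rows, cols, ks, sources, n):  # pragma: no cover - compiled
    """Global efficiency at nested edge sets.

    ``rows``/``cols`` are edges sorted by decreasing strength; candidate
    ``ks[j]`` keeps the strongest ks[j] edges. Edges are inserted
    incrementally and a BFS from each source evaluates mean 1/d per
    candidate. Returns one efficiency value per candidate.
    """
    nbr = np.empty((n, n), np.int32)
    deg = np.zeros(n, np.int32)
    egs = np.empty(ks.shape[0])
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    e = 0
    for j in range(ks.shape[0]):
        k = ks[j]
        while e < k:
            u, v = rows[e], cols[e]
            nbr[u, deg[u]] = v
            deg[u] += 1
            nbr[v, deg[v]] = u
            deg[v] += 1
            e += 1
        total = 0.0
        for si in range(sources.shape[0]):
            s = sources[si]
            for w in range(n):
                dist[w] = -1
            dist[s] = 0
            head, tail = 0, 0
            queue[tail] = s
            tail += 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for a in range(deg[u]):
                    v = nbr[u, a]
                    if dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            for w in range(n):
                if w != s and dist[w] > 0:
                    total += 1.0 / dist[w]
        egs[j] = total / (sources.shape[0] * (n - 1))
    return egs


@njit(cache=True)
def betweenness_all(indptr, indices, n):  # pragma: no cover - compiled
    """Unnormalized betweenness centrality on an undirected binary graph
    (Brandes' accumulation; each unordered pair counted once)."""
    bc = np.zeros(n)
    dist = np.empty(n, np.int32)
    sigma = np.empty(n)
    delta = np.empty(n)
    order = np.empty(n, np.int32)
    for s in range(n):
        for v in range(n):
            dist[v] = -1
            sigma[v] = 0.0
            delta[v] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        head, tail = 0, 0
        order[tail] = s
        tail += 1
        while head < tail:
            u = order[head]
            head += 1
            du = dist[u]
            for ptr in range(indptr[u], indptr[u + 1]):
                v = indices[ptr]
                if dist[v] < 0:
                    dist[v] = du + 1
                    order[tail] = v
                    tail += 1
                if dist[v] == du + 1:
                    sigma[v] += sigma[u]
        for oi in range(tail - 1, 0, -1):
            u = order[oi]
            du = dist[u]
            coef = (1.0 + delta[u]) / sigma[u]
            for ptr in range(indptr[u], indptr[u + 1]):
                v = indices[ptr]
                if dist[v] == du - 1:
                    delta[v] += sigma[v] * coef
        for v in range(n):
            if v != s:
                bc[v] += delta[v]
    return bc / 2.0


@njit(cache=True)
def path_length_stats(indptr, indices, n):  # pragma: no cover - compiled
    """Per-node (sum of finite distances, number of reachable targets)."""
    sums = np.zeros(n)
    counts = np.zeros(n, np.int64)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for s in range(n):
        for v in range(n):
            dist[v] = -1
        dist[s] = 0
        head, tail = 0, 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for ptr in range(indptr[u], indptr[u + 1]):
                v = indices[ptr]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for v in range(n):
            if v != s and dist[v] > 0:
                sums[s] += dist[v]
                counts[s] += 1
    return sums, counts


@njit(cache=True)
def local_efficiency_all(indptr, indices, n):  # pragma: no cover - compiled
    """Local efficiency per node: mean of 1/d over neighbor pairs, with
    distances measured inside the neighbor-induced subgraph."""
    out = np.zeros(n)
    loc = np.full(n, -1, np.int32)
    for i in range(n):
        k = indptr[i + 1] - indptr[i]
        if k < 2:
            continue
        nb = indices[indptr[i]:indptr[i + 1]]
        for a in range(k):
            loc[nb[a]] = a
        # adjacency lists of the neighbor-induced subgraph
        sub_deg = np.zeros(k, np.int32)
        sub_nbr = np.empty((k, k), np.int32)
        for a in range(k):
            u = nb[a]
            for ptr in range(indptr[u], indptr[u + 1]):
                lv = loc[indices[ptr]]
                if lv >= 0:
                    sub_nbr[a, sub_deg[a]] = lv
                    sub_deg[a] += 1
        total = 0.0
        dist = np.empty(k, np.int32)
        queue = np.empty(k, np.int32)
        for s in range(k):
            for v in range(k):
                dist[v] = -1
            dist[s] = 0
            head, tail = 0, 0
            queue[tail] = s
            tail += 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                for a in range(sub_deg[u]):
                    v = sub_nbr[u, a]
                    if dist[v] < 0:
                        dist[v] = du + 1
                        queue[tail] = v
                        tail += 1
            for t in range(s + 1, k):
                if dist[t] > 0:
                    total += 1.0 / dist[t]
        out[i] = total / (k * (k - 1) / 2.0)
        for a in range(k):
            loc[nb[a]] = -1
    return out
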
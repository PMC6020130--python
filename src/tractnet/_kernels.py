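"""Numba kernels for the null-model loop.

Small-worldness normalisation needs ~500 degree-preserving rewired networks per
(subject, threshold) cell, i.e. hundreds of thousands of rewire+metric evaluations
per run; these kernels keep that loop in compiled code.  All randomness is supplied
by the caller as pre-drawn arrays so results are reproducible bit-for-bit.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def rewire_stack(adj, edges, pick1, pick2, side, out):
    """Fill ``out[t]`` with degree-preserving rewirings of ``adj``.

    Each null applies a sequence of Maslov–Sneppen double-edge swaps: two edges
    (a,b), (c,d) are replaced by (a,d), (c,b) unless the swap would create a
    self-loop or a duplicate edge, in which case it is rejected.  Degree of every
    node and total edge count are invariant by construction.
    """
    n_null = out.shape[0]
    nswap = pick1.shape[1]
    n = adj.shape[0]
    for t in range(n_null):
        a_t = out[t]
        for i in range(n):
            for j in range(n):
                a_t[i, j] = adj[i, j]
        ed = edges.copy()
        for s in range(nswap):
            i = pick1[t, s]
            j = pick2[t, s]
            if i == j:
                continue
            a = ed[i, 0]
            b = ed[i, 1]
            c = ed[j, 0]
            d = ed[j, 1]
            if side[t, s] == 1:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            if a_t[a, d] or a_t[c, b]:
                continue
            a_t[a, b] = False
            a_t[b, a] = False
            a_t[c, d] = False
            a_t[d, c] = False
            a_t[a, d] = True
            a_t[d, a] = True
            a_t[c, b] = True
            a_t[b, c] = True
            ed[i, 0] = a
            ed[i, 1] = d
            ed[j, 0] = c
            ed[j, 1] = b


@njit(cache=True)
def mean_clustering(adj):
    """Mean over nodes of the binary clustering coefficient (0 for degree < 2)."""
    n = adj.shape[0]
    total = 0.0
    for v in range(n):
        k = 0
        for i in range(n):
            if adj[v, i]:
                k += 1
        if k < 2:
            continue
        tri = 0
        for i in range(n):
            if not adj[v, i]:
                continue
            for j in range(i + 1, n):
                if adj[v, j] and adj[i, j]:
                    tri += 1
        total += 2.0 * tri / (k * (k - 1.0))
    return total / n


@njit(cache=True)
def pairwise_distances(adj):
    """All-pairs BFS geodesic distances; -1 marks unreachable pairs."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    for s in range(n):
        dist[s, s] = 0
        head = 0
        tail = 0
        queue[tail] = s
        tail += 1
        while head < tail:
            u = queue[head]
            head += 1
            for v in range(n):
                if adj[u, v] and dist[s, v] < 0:
                    dist[s, v] = dist[s, u] + 1
                    queue[tail] = v
                    tail += 1
    return dist


@njit(cache=True)
def char_path_length(adj):
    """Mean geodesic distance over connected (reachable) ordered pairs."""
    dist = pairwise_distances(adj)
    n = adj.shape[0]
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(n):
            if i != j and dist[i, j] > 0:
                total += dist[i, j]
                count += 1
    if count == 0:
        return 0.0
    return total / count


@njit(cache=True)
def null_stats(stack):
    """Per-null mean clustering and characteristic path length."""
    n = stack.shape[0]
    c = np.empty(n, dtype=np.float64)
    l = np.empty(n, dtype=np.float64)
    for t in range(n):
        c[t] = mean_clustering(stack[t])
        l[t] = char_path_length(stack[t])
    return c, l
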
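"""Brute-force graph-metric oracles by exhaustive path enumeration.

Independent of the package's implementations (and of networkx's algorithms):
shortest paths are found by enumerating ALL simple paths with a hand-rolled
DFS, so these oracles are only usable on tiny graphs (<= 8 nodes or so).
"""

import numpy as np


def all_simple_paths(adj, s, t):
    """Every simple path from s to t as a list of node lists."""
    n = adj.shape[0]
    paths = []

    def _dfs(node, visited, path):
        if node == t:
            paths.append(list(path))
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                _dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    _dfs(s, {s}, [s])
    return paths


def shortest_paths(adj, s, t):
    """(geodesic length, list of shortest simple paths); (inf, []) if none."""
    paths = all_simple_paths(adj, s, t)
    if not paths:
        return np.inf, []
    d = min(len(p) - 1 for p in paths)
    return d, [p for p in paths if len(p) - 1 == d]


def distance_matrix(adj):
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for s in range(n):
        for t in range(n):
            if s != t:
                dist[s, t] = shortest_paths(adj, s, t)[0]
    return dist


def degree(adj):
    return adj.sum(axis=1).astype(int)


def density(adj):
    n = adj.shape[0]
    return adj.sum() / (n * (n - 1)) if n > 1 else 0.0


def betweenness(adj):
    """Unnormalized betweenness; each unordered pair counted once."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            _d, sps = shortest_paths(adj, s, t)
            if not sps:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in sps if v in p[1:-1])
                bc[v] += through / len(sps)
    return bc


def path_length_nodal(adj):
    dist = distance_matrix(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        d = dist[v]
        reach = np.isfinite(d) & (d > 0)
        if reach.any():
            out[v] = d[reach].mean()
    return out


def char_path_length(adj):
    dist = distance_matrix(adj)
    off = dist[~np.eye(adj.shape[0], dtype=bool)]
    finite = off[np.isfinite(off)]
    return finite.mean() if finite.size else 0.0


def global_efficiency(adj):
    dist = distance_matrix(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))


def clustering(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if adj[nbrs[a], nbrs[b]]
        )
        out[v] = 2 * tri / (k * (k - 1))
    return out


def local_efficiency(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[v] = global_efficiency(sub)
    return out


def assortativity(adj):
    """Pearson correlation of endpoint degrees over both edge orientations."""
    deg = degree(adj)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    if not xs:
        return np.nan
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])
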
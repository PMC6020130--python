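"""Binary graph metrics on thresholded structural connectomes.

The weighted 24x24 connectivity matrices are reduced to binary networks by
proportional thresholding (keep the strongest fraction of possible edges, so
every subject's network has identical density at a given level), and nine graph
metrics are computed on the binary network: degree, density, betweenness
centrality, nodal characteristic path length, clustering coefficient, local
efficiency, global efficiency, assortativity and small-worldness.

Small-worldness is normalised against an ensemble of degree-preserving rewired
null networks: gamma = C / <C_null>, lambda = L / <L_null>, sigma = gamma /
lambda, with sigma > 1 indicating small-world organisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import _kernels

__all__ = [
    "BinaryNetwork",
    "NullEnsemble",
    "threshold_grid",
    "proportional_threshold",
    "degree",
    "density",
    "betweenness_centrality",
    "characteristic_path_length_nodal",
    "reachable_fraction",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "assortativity",
    "generate_nulls",
    "small_worldness",
    "detect_hubs",
    "ring_lattice_network",
    "NODAL_METRICS",
    "GLOBAL_METRICS",
]

NODAL_METRICS = (
    "degree",
    "betweenness",
    "path_length",
    "clustering",
    "local_efficiency",
)
GLOBAL_METRICS = ("density", "global_efficiency", "assortativity", "small_worldness")


@dataclass
class BinaryNetwork:
    """Undirected binary network with the proportional threshold that produced it."""

    adjacency: np.ndarray
    threshold_level: float | None = None

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency, 1))))
        return g


@dataclass
class NullEnsemble:
    """Stack of degree-preserving rewired networks derived from one source network."""

    adjacency: np.ndarray  # (n_null, n, n) boolean
    source: np.ndarray  # (n, n) boolean
    seed: int
    swaps_per_edge: int = 10
    identical_to_source: bool = field(default=False)

    @property
    def n_null(self) -> int:
        return self.adjacency.shape[0]


def _adj(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net, dtype=bool)


def threshold_grid(lo: float = 0.15, hi: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Proportional-threshold levels from `lo` to `hi` inclusive in steps of `step`."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 10)


def proportional_threshold(weights: np.ndarray, level: float) -> BinaryNetwork:
    """Binarize a weighted matrix keeping the strongest `level` fraction of edges.

    Exactly ``k = round(level * N(N-1)/2)`` off-diagonal edges are retained
    (round half to even); ties are broken by lexicographic edge order so the
    result is reproducible.  If fewer than k weights are nonzero, all nonzero
    edges are kept and a warning is emitted.
    """
    w_mat = np.asarray(weights, dtype=float)
    if w_mat.ndim != 2 or w_mat.shape[0] != w_mat.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w_mat, w_mat.T):
        raise ValueError("weights must be symmetric")
    if not np.allclose(np.diag(w_mat), 0.0):
        raise ValueError("weights must have a zero diagonal")
    if not 0.0 < level <= 1.0:
        raise ValueError(f"threshold level must be in (0, 1], got {level}")

    n = w_mat.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = w_mat[iu, ju]
    m = w.size
    k = round(level * m)

    order = np.lexsort((ju, iu, -w))  # strongest first, ties lexicographic
    nonzero_in_order = order[w[order] > 0]
    if nonzero_in_order.size < k:
        warnings.warn(
            f"only {nonzero_in_order.size} nonzero weights available for "
            f"level {level} (k={k}); retaining all nonzero edges",
            stacklevel=2,
        )
        kept = nonzero_in_order
    else:
        kept = nonzero_in_order[:k]

    adj = np.zeros((n, n), dtype=bool)
    adj[iu[kept], ju[kept]] = True
    adj |= adj.T
    return BinaryNetwork(adj, threshold_level=level)


# ---------------------------------------------------------------------------
# the nine metrics


def degree(net) -> np.ndarray:
    return _adj(net).sum(axis=1).astype(int)


def density(net) -> float:
    adj = _adj(net)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    return float(adj.sum() / (n * (n - 1)))


def betweenness_centrality(net) -> np.ndarray:
    """Unnormalized betweenness (each unordered source–target pair counted once)."""
    net = net if isinstance(net, BinaryNetwork) else BinaryNetwork(_adj(net))
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return np.array([bc[v] for v in range(net.n_nodes)])


def characteristic_path_length_nodal(net) -> np.ndarray:
    """Mean geodesic distance from each node to the nodes it can reach.

    Unreachable nodes contribute nothing to the average (see
    :func:`reachable_fraction` for how much of the network each node reaches);
    an isolated node gets path length 0.
    """
    adj = np.ascontiguousarray(_adj(net))
    dist = _kernels.pairwise_distances(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        d = dist[v]
        reach = d > 0
        if reach.any():
            out[v] = d[reach].mean()
    return out


def reachable_fraction(net) -> np.ndarray:
    """Fraction of the other nodes each node can reach."""
    adj = np.ascontiguousarray(_adj(net))
    dist = _kernels.pairwise_distances(adj)
    n = adj.shape[0]
    return (dist > 0).sum(axis=1) / (n - 1)


def global_efficiency(net) -> float:
    """Mean inverse geodesic distance over all ordered node pairs (1/inf = 0)."""
    net = net if isinstance(net, BinaryNetwork) else BinaryNetwork(_adj(net))
    return float(nx.global_efficiency(net.to_networkx()))


def local_efficiency(net) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph (0 if < 2 neighbours)."""
    net = net if isinstance(net, BinaryNetwork) else BinaryNetwork(_adj(net))
    g = net.to_networkx()
    out = np.zeros(net.n_nodes)
    for v in range(net.n_nodes):
        nbrs = list(g[v])
        if len(nbrs) >= 2:
            out[v] = nx.global_efficiency(g.subgraph(nbrs))
    return out


def clustering_coefficient(net) -> np.ndarray:
    net = net if isinstance(net, BinaryNetwork) else BinaryNetwork(_adj(net))
    cc = nx.clustering(net.to_networkx())
    return np.array([cc[v] for v in range(net.n_nodes)])


def assortativity(net) -> float:
    """Degree assortativity (Pearson correlation of degrees over edge endpoints).

    Returns NaN with a warning when undefined (zero degree variance over edges,
    e.g. any regular graph, or no edges).
    """
    net = net if isinstance(net, BinaryNetwork) else BinaryNetwork(_adj(net))
    g = net.to_networkx()
    if g.number_of_edges() == 0:
        warnings.warn("assortativity undefined: network has no edges", stacklevel=2)
        return float("nan")
    deg = dict(g.degree())
    end_degrees = [deg[u] for e in g.edges() for u in e]
    if len(set(end_degrees)) == 1:
        warnings.warn(
            "assortativity undefined: zero degree variance over edges", stacklevel=2
        )
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = nx.degree_assortativity_coefficient(g)
    return float(r)


# ---------------------------------------------------------------------------
# null models and small-worldness


def _has_independent_edge_pair(edges: np.ndarray) -> bool:
    for i in range(len(edges)):
        a, b = edges[i]
        for j in range(i + 1, len(edges)):
            c, d = edges[j]
            if a != c and a != d and b != c and b != d:
                return True
    return False


def generate_nulls(
    net, n_null: int = 500, swaps_per_edge: int = 10, seed: int = 0
) -> NullEnsemble:
    """Degree-preserving null networks by Maslov–Sneppen double-edge swaps.

    Every null has exactly the node count, edge count and degree sequence of the
    source network.  If no valid swap exists (e.g. complete graph, star), the
    ensemble is n_null copies of the source and a warning is emitted.
    """
    adj = np.ascontiguousarray(_adj(net))
    edges = np.argwhere(np.triu(adj, 1)).astype(np.int64)
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("null generation requires a network with >= 2 edges")

    stack = np.empty((n_null, adj.shape[0], adj.shape[1]), dtype=bool)
    if not _has_independent_edge_pair(edges):
        warnings.warn(
            "no valid degree-preserving swap exists; nulls are copies of the source",
            stacklevel=2,
        )
        stack[:] = adj
        return NullEnsemble(stack, adj, seed, swaps_per_edge, identical_to_source=True)

    nswap = swaps_per_edge * n_edges
    rng = np.random.default_rng(seed)
    pick1 = rng.integers(0, n_edges, size=(n_null, nswap))
    pick2 = rng.integers(0, n_edges, size=(n_null, nswap))
    side = rng.integers(0, 2, size=(n_null, nswap))
    _kernels.rewire_stack(adj, edges, pick1, pick2, side, stack)
    return NullEnsemble(stack, adj, seed, swaps_per_edge)


def small_worldness(net, nulls: NullEnsemble) -> tuple[float, float, float]:
    """(gamma, lambda, sigma) of a network against its null ensemble.

    gamma = mean clustering / null mean; lambda = characteristic path length /
    null mean; sigma = gamma / lambda.  NaN with a warning if a null mean is zero.
    """
    adj = np.ascontiguousarray(_adj(net))
    c_obs = _kernels.mean_clustering(adj)
    l_obs = _kernels.char_path_length(adj)
    c_null, l_null = _kernels.null_stats(np.ascontiguousarray(nulls.adjacency))
    c_bar = c_null.mean()
    l_bar = l_null.mean()
    if c_bar == 0.0 or l_bar == 0.0:
        warnings.warn("small-worldness undefined: zero null mean", stacklevel=2)
        return float("nan"), float("nan"), float("nan")
    # self-normalization is exactly 1 (no accumulation error when every null
    # carries the observed value)
    gamma = 1.0 if np.all(c_null == c_obs) else c_obs / c_bar
    lam = 1.0 if np.all(l_null == l_obs) else l_obs / l_bar
    return float(gamma), float(lam), float(gamma / lam)


def detect_hubs(
    mean_degree: np.ndarray, mean_betweenness: np.ndarray, z_thresh: float = 2.0
) -> np.ndarray:
    """Hub nodes: z-score >= z_thresh across nodes on BOTH degree and betweenness."""
    d = np.asarray(mean_degree, dtype=float)
    b = np.asarray(mean_betweenness, dtype=float)
    if d.shape != b.shape:
        raise ValueError("degree and betweenness vectors must have equal length")
    sd_d = d.std(ddof=1)
    sd_b = b.std(ddof=1)
    if sd_d == 0.0 or sd_b == 0.0:
        warnings.warn("zero variance across nodes; no hubs detected", stacklevel=2)
        return np.array([], dtype=int)
    z_d = (d - d.mean()) / sd_d
    z_b = (b - b.mean()) / sd_b
    return np.nonzero((z_d >= z_thresh) & (z_b >= z_thresh))[0]


def ring_lattice_network(
    n_nodes: int = 24,
    level: float = 0.25,
    rewire_frac: float = 0.10,
    seed: int = 0,
) -> BinaryNetwork:
    """Ring lattice with random shortcuts, density-matched to a threshold level.

    A ring-lattice weight matrix (weight decays with ring distance, tiny random
    jitter to break band ties) is proportionally thresholded at `level`, then a
    `rewire_frac` fraction of the retained edges is replaced by uniformly random
    shortcuts.  The result is a small-world benchmark network: high clustering
    from the lattice, short paths from the shortcuts.
    """
    rng = np.random.default_rng(seed)
    idx = np.arange(n_nodes)
    ring_dist = np.abs(idx[:, None] - idx[None, :])
    ring_dist = np.minimum(ring_dist, n_nodes - ring_dist).astype(float)
    with np.errstate(divide="ignore"):
        w = np.where(ring_dist > 0, 1.0 / ring_dist, 0.0)
    jitter = rng.uniform(0, 1e-6, size=(n_nodes, n_nodes))
    jitter = np.triu(jitter, 1)
    w = w + jitter + jitter.T
    np.fill_diagonal(w, 0.0)
    net = proportional_threshold(w, level)

    adj = net.adjacency.copy()
    edges = np.argwhere(np.triu(adj, 1))
    n_rewire = int(round(rewire_frac * len(edges)))
    chosen = rng.choice(len(edges), size=n_rewire, replace=False)
    for e in chosen:
        a, b = edges[e]
        adj[a, b] = adj[b, a] = False
    for _ in range(n_rewire):
        while True:
            u, v = rng.integers(0, n_nodes, size=2)
            if u != v and not adj[u, v]:
                adj[u, v] = adj[v, u] = True
                break
    return BinaryNetwork(adj, threshold_level=level)
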
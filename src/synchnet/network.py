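"""Proportional thresholding and weighted small-world graph metrics.

A synchrony matrix is reduced to a weighted graph by keeping its K largest
off-diagonal entries.  Segregation (weighted clustering), integration
(characteristic path length over 1/weight edge lengths) and the
small-worldness index sigma = gamma / lambda are evaluated against
degree-preserving rewired null networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .phasesync import PSIMatrix

__all__ = [
    "WeightedGraph",
    "NetworkSummary",
    "threshold_graph",
    "node_degree",
    "clustering_coefficient",
    "char_path_length",
    "rewire_random",
    "small_world_indices",
    "density_sweep",
]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with exactly K off-diagonal edges."""

    labels: list[str]
    weights: np.ndarray
    k: int
    threshold: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0:
            raise ValueError("weights must be nonnegative")
        iu = np.triu_indices(w.shape[0], k=1)
        n_edges = int(np.count_nonzero(w[iu]))
        if n_edges != self.k:
            raise ValueError(f"graph has {n_edges} edges, expected K={self.k}")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def max_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def density(self) -> float:
        return self.k / self.max_edges

    def edge_list(self) -> list[tuple[int, int, float]]:
        iu, ju = np.triu_indices(self.n, k=1)
        mask = self.weights[iu, ju] > 0
        return [
            (int(i), int(j), float(self.weights[i, j]))
            for i, j in zip(iu[mask], ju[mask])
        ]


@dataclass
class NetworkSummary:
    """Metrics of one graph at one density level, with its rewired-null norms."""

    k: int
    density: float
    degree: np.ndarray
    clustering: float
    path_length: float
    c_rand: float
    l_rand: float
    gamma: float
    lambda_: float
    sigma: float
    n_random: int
    seed: int | None = None
    labels: list[str] = field(default_factory=list)


def threshold_graph(psi: PSIMatrix | np.ndarray, k: int,
                    labels: list[str] | None = None) -> WeightedGraph:
    """Keep the K largest off-diagonal entries (with their weights).

    The threshold is the K-th largest synchrony value.  Ties at the
    threshold are broken deterministically — descending value, then
    ascending (i, j) pair — so exactly K edges are always retained.
    """
    if isinstance(psi, PSIMatrix):
        values, labels = psi.values, list(psi.channels)
    else:
        values = np.asarray(psi, dtype=float)
        labels = list(labels) if labels is not None else [
            f"N{i}" for i in range(values.shape[0])
        ]
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size
    if not 1 <= k <= m:
        raise ValueError(f"K={k} outside [1, {m}]")
    vals = values[iu, ju]
    order = np.lexsort((ju, iu, -vals))  # primary: value desc; then (i, j) asc
    keep = order[:k]
    w = np.zeros_like(values)
    w[iu[keep], ju[keep]] = vals[keep]
    w = w + w.T
    return WeightedGraph(labels=labels, weights=w, k=k,
                         threshold=float(vals[order[k - 1]]))


def node_degree(graph: WeightedGraph) -> np.ndarray:
    """Weighted degree (strength) D_i = sum_j w_ij."""
    return graph.weights.sum(axis=1)


def clustering_coefficient(graph: WeightedGraph, mode: str = "onnela") -> float:
    """Mean weighted clustering coefficient.

    ``onnela``: C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)
    with weights normalized by the network maximum and k_i the number of
    nonzero neighbours; nodes with k_i < 2 contribute 0.

    ``literal``: same triangle numerator but divided by D_i (D_i - 1) with
    the weighted degree D_i, as an alternative normalization.
    """
    w = graph.weights
    if graph.n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    wmax = w.max()
    if wmax == 0:
        return 0.0
    what = np.cbrt(w / wmax)
    numer = np.diagonal(what @ what @ what)  # ordered-pair triangle sum per node
    if mode == "onnela":
        kdeg = (w > 0).sum(axis=1).astype(float)
        denom = kdeg * (kdeg - 1)
    elif mode == "literal":
        deg = w.sum(axis=1)
        denom = deg * (deg - 1)
    else:
        raise ValueError(f"unknown clustering mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, numer / denom, 0.0)
    return float(ci.mean())


def _shortest_paths(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    w = graph.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def char_path_length(graph: WeightedGraph, mode: str = "harmonic") -> float:
    """Characteristic path length over 1/weight edge lengths.

    ``harmonic``: inverse of the mean of 1/d_ij over ordered pairs i != j,
    with disconnected pairs contributing 0 (robust to disconnection).
    ``arithmetic``: plain mean of d_ij (infinite if disconnected).
    """
    if graph.n < 2:
        raise ValueError("path length needs at least 2 nodes")
    d = _shortest_paths(graph)
    off = ~np.eye(graph.n, dtype=bool)
    dij = d[off]
    if mode == "harmonic":
        with np.errstate(divide="ignore"):
            inv = np.where(np.isinf(dij), 0.0, 1.0 / dij)
        mean_inv = inv.mean()
        return float(np.inf) if mean_inv == 0 else float(1.0 / mean_inv)
    if mode == "arithmetic":
        return float(dij.mean())
    raise ValueError(f"unknown path-length mode {mode!r}")


def rewire_random(
    graph: WeightedGraph,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    effort: int = 10,
) -> WeightedGraph:
    """Degree-preserving null network via double-edge swaps.

    ``effort * K`` swap attempts randomize the binary topology while keeping
    every node's binary degree exact; the multiset of edge weights is then
    randomly reassigned to the rewired edges.  Self-loops and multi-edges are
    never created.  A graph admitting no valid swap is returned unchanged
    with a warning.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges = [(i, j) for i, j, _ in graph.edge_list()]
    weights = np.array([w for _, _, w in graph.edge_list()])
    k = len(edges)
    if k < 2:
        warnings.warn("graph has fewer than 2 edges; cannot rewire")
        return WeightedGraph(list(graph.labels), graph.weights.copy(),
                             graph.k, graph.threshold)
    edge_set = set(edges)
    n_swapped = 0
    for _ in range(effort * k):
        a_idx, b_idx = rng.choice(k, size=2, replace=False)
        (u, v), (x, y) = edges[a_idx], edges[b_idx]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u, y) and (x, v)
        e1 = (min(u, y), max(u, y))
        e2 = (min(x, v), max(x, v))
        if u == y or x == v:
            continue
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[a_idx])
        edge_set.discard(edges[b_idx])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a_idx], edges[b_idx] = e1, e2
        n_swapped += 1
    if n_swapped == 0:
        warnings.warn("no valid double-edge swap found; returning input graph")
        return WeightedGraph(list(graph.labels), graph.weights.copy(),
                             graph.k, graph.threshold)
    perm = rng.permutation(k)
    w = np.zeros_like(graph.weights)
    for (i, j), wt in zip(edges, weights[perm]):
        w[i, j] = wt
        w[j, i] = wt
    return WeightedGraph(list(graph.labels), w, graph.k, graph.threshold)


def small_world_indices(
    graph: WeightedGraph,
    n_random: int = 20,
    seed: int | np.random.SeedSequence = 0,
    clustering_mode: str = "onnela",
    path_mode: str = "harmonic",
    effort: int = 10,
) -> NetworkSummary:
    """C, L and their rewired-null normalizations gamma, lambda, sigma.

    C_rand and L_rand are means over ``n_random`` independently rewired
    graphs (per-null seeds split from the master seed); gamma = C / C_rand,
    lambda = L / L_rand, sigma = gamma / lambda.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    c = clustering_coefficient(graph, clustering_mode)
    l = char_path_length(graph, path_mode)
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    c_rands, l_rands = [], []
    for child in ss.spawn(n_random):
        null = rewire_random(graph, seed=child, effort=effort)
        c_rands.append(clustering_coefficient(null, clustering_mode))
        l_rands.append(char_path_length(null, path_mode))
    c_rand = float(np.mean(c_rands))
    l_rand = float(np.mean(l_rands))
    if c_rand == 0:
        raise ZeroDivisionError("degenerate null: C_rand = 0")
    gamma = c / c_rand
    lambda_ = l / l_rand
    return NetworkSummary(
        k=graph.k,
        density=graph.density,
        degree=node_degree(graph),
        clustering=c,
        path_length=l,
        c_rand=c_rand,
        l_rand=l_rand,
        gamma=gamma,
        lambda_=lambda_,
        sigma=gamma / lambda_,
        n_random=n_random,
        seed=ss.entropy if isinstance(ss.entropy, int) else None,
        labels=list(graph.labels),
    )


def density_sweep(
    psi: PSIMatrix,
    k_list: tuple[int, ...],
    n_random: int = 20,
    seed: int | np.random.SeedSequence = 0,
    clustering_mode: str = "onnela",
    path_mode: str = "harmonic",
) -> list[NetworkSummary]:
    """One :class:`NetworkSummary` per edge number in ``k_list``."""
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    out = []
    for k, child in zip(k_list, ss.spawn(len(k_list))):
        graph = threshold_graph(psi, k)
        out.append(
            small_world_indices(
                graph,
                n_random=n_random,
                seed=child,
                clustering_mode=clustering_mode,
                path_mode=path_mode,
            )
        )
    return out
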
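"""Signed-aware weighted graph metrics on fully connected networks.

The pipeline keeps negative correlations by soft-thresholding rather
than hard-thresholding: correlations r in [-1, 1] map continuously to
weights w = ((r + 1) / 2) ** beta in [0, 1], suppressing (not removing)
weak and negative links.  All metrics below operate on that dense
weighted graph:

* Louvain community detection (best of n seeded runs by modularity),
* the participation coefficient PC_i = 1 - sum_s (kappa_is / k_i)^2,
* nodal and edge betweenness centrality under the length transform
  length = 1 / w (strong links are short), unnormalized, and
* small-worldness sigma = gamma / lambda against degree-preserving
  rewired null networks, computed on a binarized network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "SoftThresholdedGraph",
    "CommunityPartition",
    "NodeGraphMetrics",
    "SmallWorldStats",
    "soft_threshold",
    "louvain_partition",
    "participation_coefficient",
    "nodal_betweenness",
    "edge_betweenness",
    "small_worldness",
    "maslov_sneppen_rewire",
]

DEFAULT_BETA = 12


@dataclass
class SoftThresholdedGraph:
    """Dense nonnegative weights from the power soft-threshold mapping."""

    weights: np.ndarray
    beta_exponent: int
    source_r: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_networkx(self) -> nx.Graph:
        """Weighted graph with a ``length = 1/weight`` attribute per edge."""
        g = nx.Graph()
        n = self.n_nodes
        g.add_nodes_from(range(n))
        w = self.weights
        for i in range(n):
            for j in range(i + 1, n):
                if w[i, j] > 0:
                    g.add_edge(i, j, weight=w[i, j], length=1.0 / w[i, j])
        return g


@dataclass
class CommunityPartition:
    assignment: np.ndarray  # community id per node, contiguous from 1
    n_communities: int
    modularity_q: float


@dataclass
class NodeGraphMetrics:
    participation: np.ndarray
    nodal_betweenness: np.ndarray


@dataclass
class SmallWorldStats:
    """gamma = C/C_null, lambda = L/L_null, sigma = gamma/lambda."""

    gamma: float
    lam: float
    sigma: float
    n_null: int
    null_seed: int
    flagged: bool = False


def soft_threshold(r_matrix: np.ndarray, beta: int = DEFAULT_BETA) -> SoftThresholdedGraph:
    """Map correlations to nonnegative weights, w_ij = ((r_ij + 1)/2) ** beta.

    The mapping is strictly increasing in r, sends r = -1 to 0 and
    r = 1 to 1, and keeps the graph fully connected (every w > 0 for
    r > -1).  Input entries must lie in [-1, 1]; Fisher-z values must
    be back-transformed (tanh) first.
    """
    r = np.asarray(r_matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("expected a square correlation matrix")
    if np.any(np.abs(r) > 1.0):
        raise ValueError(
            "correlations outside [-1, 1]; if these are Fisher-z values, "
            "back-transform with tanh before soft-thresholding"
        )
    if beta <= 0 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    w = ((r + 1.0) / 2.0) ** beta
    np.fill_diagonal(w, 0.0)
    return SoftThresholdedGraph(weights=w, beta_exponent=int(beta), source_r=r.copy())


def louvain_partition(graph: SoftThresholdedGraph, n_runs: int = 20,
                      seed: int = 0) -> CommunityPartition:
    """Best-of-n Louvain modularity partition (deterministic given seed)."""
    if graph.n_nodes == 0:
        raise ValueError("cannot partition an empty graph")
    if np.any(graph.weights < 0):
        raise ValueError("Louvain requires nonnegative weights")
    g = nx.from_numpy_array(graph.weights)
    best_q, best = -np.inf, None
    for k in range(n_runs):
        communities = nx.community.louvain_communities(
            g, weight="weight", seed=seed + k, resolution=1.0
        )
        q = nx.community.modularity(g, communities, weight="weight")
        if q > best_q:
            best_q, best = q, communities
    assignment = np.empty(graph.n_nodes, dtype=int)
    for cid, nodes in enumerate(sorted(best, key=min), start=1):
        for v in nodes:
            assignment[v] = cid
    return CommunityPartition(assignment=assignment, n_communities=len(best),
                              modularity_q=float(best_q))


def participation_coefficient(graph: SoftThresholdedGraph,
                              partition: CommunityPartition) -> np.ndarray:
    """PC_i = 1 - sum_s (kappa_is / k_i)^2 over communities s.

    kappa_is is node i's summed weight into community s and k_i its
    strength; isolated nodes (k_i = 0) get PC = 0.
    """
    w = graph.weights
    if partition.assignment.shape[0] != w.shape[0]:
        raise ValueError("partition does not cover the graph's nodes")
    k = w.sum(axis=1)
    pc = np.zeros(w.shape[0])
    nz = k > 0
    for cid in np.unique(partition.assignment):
        kappa = w[:, partition.assignment == cid].sum(axis=1)
        pc[nz] += (kappa[nz] / k[nz]) ** 2
    pc[nz] = 1.0 - pc[nz]
    # clip tiny negative rounding
    return np.clip(pc, 0.0, 1.0)


def nodal_betweenness(graph: SoftThresholdedGraph) -> np.ndarray:
    """Unnormalized shortest-path betweenness per node, lengths = 1/w.

    Counts unordered source-target pairs with endpoints excluded and
    fractional credit shared across equal-length shortest paths.
    """
    g = graph.to_networkx()
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(graph.n_nodes)])


def edge_betweenness(graph: SoftThresholdedGraph) -> np.ndarray:
    """Unnormalized edge betweenness matrix under the same conventions.

    An entry is positive iff the edge lies on at least one shortest
    path (every edge is on the path of its own endpoints unless a
    strictly shorter detour exists).  Non-edges (w = 0) get 0.
    """
    g = graph.to_networkx()
    ebc = nx.edge_betweenness_centrality(g, weight="length", normalized=False)
    out = np.zeros_like(graph.weights)
    for (i, j), v in ebc.items():
        out[i, j] = v
        out[j, i] = v
    return out


def maslov_sneppen_rewire(g: nx.Graph, n_attempts: int,
                          rng: np.random.Generator) -> nx.Graph:
    """Degree-preserving rewiring by repeated double-edge swap attempts."""
    h = g.copy()
    edges = list(h.edges())
    if len(edges) < 2:
        return h
    for _ in range(n_attempts):
        (a, b), (c, d) = (edges[rng.integers(len(edges))],
                          edges[rng.integers(len(edges))])
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, d)
        h.add_edge(c, b)
        edges = list(h.edges())
    return h


def _clustering_and_path_length(g: nx.Graph) -> tuple[float, float]:
    """Mean clustering coefficient and mean shortest-path length over
    connected pairs of a binary graph; L is nan if no pair is connected."""
    if g.number_of_nodes() == 0:
        return np.nan, np.nan
    c = nx.average_clustering(g)
    total, count = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    lam = total / count if count else np.nan
    return c, lam


def small_worldness(adjacency: np.ndarray, n_null: int = 50, seed: int = 0,
                    nulls: list[nx.Graph] | None = None) -> SmallWorldStats:
    """Small-worldness sigma = gamma / lambda of a binary network.

    gamma is the clustering ratio and lambda the characteristic
    path-length ratio against an ensemble of degree-preserving
    (Maslov-Sneppen) rewired null graphs, 10 * |E| swap attempts each.
    A triangle-free network has gamma = 0 and hence sigma = 0; if the
    null ensemble itself has zero clustering while the network does
    not, the ratio is undefined and the result is flagged (nan).

    ``nulls`` overrides the generated ensemble (e.g. for self-null
    identity checks).
    """
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.shape[0] < 4:
        raise ValueError("small-worldness needs at least 4 nodes")
    if nulls is None and n_null < 20:
        raise ValueError("need at least 20 null networks")
    g = nx.from_numpy_array((a != 0).astype(int))
    g.remove_edges_from(nx.selfloop_edges(g))
    c, lam = _clustering_and_path_length(g)

    if nulls is None:
        ss = np.random.SeedSequence(seed)
        nulls = [
            maslov_sneppen_rewire(g, 10 * g.number_of_edges(),
                                  np.random.default_rng(child))
            for child in ss.spawn(n_null)
        ]
    null_stats = np.array([_clustering_and_path_length(h) for h in nulls])
    c_null = float(np.nanmean(null_stats[:, 0]))
    l_null = float(np.nanmean(null_stats[:, 1]))

    flagged = False
    if c == 0.0:
        gamma = 0.0
    elif c_null > 0.0:
        gamma = c / c_null
    else:
        gamma, flagged = np.nan, True
    if np.isfinite(lam) and np.isfinite(l_null) and l_null > 0:
        lam_ratio = lam / l_null
    else:
        lam_ratio, flagged = np.nan, True
    sigma = gamma / lam_ratio if np.isfinite(gamma) and np.isfinite(lam_ratio) \
        else np.nan
    if not np.isfinite(sigma):
        flagged = True
    return SmallWorldStats(gamma=float(gamma), lam=float(lam_ratio),
                           sigma=float(sigma), n_null=len(nulls),
                           null_seed=seed, flagged=flagged)
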
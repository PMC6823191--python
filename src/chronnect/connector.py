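"""Connector-hub classification, signed sparsification, and backbone extraction.

A *connector hub* is a node whose links spread across several
communities: participation coefficient above threshold with nonzero
nodal and edge betweenness, at every within-trial time point of a
condition.  Classified hubs are pruned to those keeping at least one
nonzero-edge-betweenness link to another retained hub in a different
community (iterated to a fixed point, since removals can isolate
previously supported hubs).

The full correlation graph is then *sparsified by edge betweenness*:
the binarized edge-betweenness matrix masks the signed group
connectivity matrix, so an edge survives exactly when it lies on at
least one shortest path, while its connectivity value - including its
sign - is carried through unchanged.  Negative intermodular links are
thereby preserved rather than thresholded away.

The *functional backbone* is the set of hubs shared by every
condition, together with the per-condition edges stable across all
time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dcc import GroupConnectivityMatrix
from .graph import CommunityPartition, NodeGraphMetrics

__all__ = [
    "TimePointMetrics",
    "ConnectorHubSet",
    "ConnectorNetwork",
    "FunctionalBackbone",
    "SignSummary",
    "classify_connector_hubs",
    "prune_isolated_connectors",
    "sparsify_by_edge_betweenness",
    "extract_backbone",
    "intermodular_sign_summary",
]


@dataclass
class TimePointMetrics:
    """Graph metrics of the full network at one (condition, time index)."""

    partition: CommunityPartition
    metrics: NodeGraphMetrics
    edge_bc: np.ndarray


@dataclass
class ConnectorHubSet:
    condition: str
    hubs: tuple[int, ...]  # node indices, sorted
    # per time index: node -> (participation, nodal_bc, community)
    records: dict[int, dict[int, tuple[float, float, int]]] = field(default_factory=dict)


@dataclass
class ConnectorNetwork:
    """Signed sparse network over connector hubs at one condition/time point."""

    condition: str
    time_index: int
    nodes: tuple[int, ...]
    signed_edges: list[tuple[int, int, float]]  # (i, j, group z value), i < j
    communities: dict[int, int]

    def adjacency(self) -> np.ndarray:
        """Binary adjacency over ``nodes`` (in their listed order)."""
        idx = {v: k for k, v in enumerate(self.nodes)}
        a = np.zeros((len(self.nodes), len(self.nodes)), dtype=int)
        for i, j, _ in self.signed_edges:
            a[idx[i], idx[j]] = a[idx[j], idx[i]] = 1
        return a

    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((i, j) for i, j, _ in self.signed_edges)


@dataclass
class FunctionalBackbone:
    shared_hubs: tuple[int, ...]
    stable_edges: dict[str, frozenset[tuple[int, int]]]
    condition_patterns: dict[str, np.ndarray]


@dataclass
class SignSummary:
    condition: str
    time_index: int
    n_intermodular: int
    n_negative: int

    @property
    def fraction_negative(self) -> float | None:
        if self.n_intermodular == 0:
            return None
        return self.n_negative / self.n_intermodular


def _passes_rule(metrics: TimePointMetrics, node: int, pc_threshold: float) -> bool:
    m = metrics.metrics
    return (
        m.participation[node] > pc_threshold
        and m.nodal_betweenness[node] != 0
        and np.any(metrics.edge_bc[node] != 0)
    )


def prune_isolated_connectors(
    hubs: set[int], edge_bc: np.ndarray, partition: CommunityPartition
) -> set[int]:
    """Drop hubs without a nonzero-edge-BC link to a retained hub in a
    different community; iterate until a fixed point (removals can
    strand hubs that previously had support)."""
    retained = set(hubs)
    changed = True
    while changed:
        changed = False
        for v in sorted(retained):
            supported = any(
                edge_bc[v, u] != 0
                and partition.assignment[u] != partition.assignment[v]
                for u in retained
                if u != v
            )
            if not supported:
                retained.discard(v)
                changed = True
    return retained


def classify_connector_hubs(
    condition: str,
    metrics_by_time: dict[int, TimePointMetrics],
    pc_threshold: float = 0.5,
    mode: str = "all",
) -> ConnectorHubSet:
    """Classify connector hubs for one condition across its time points.

    A node qualifies when participation > ``pc_threshold`` and both
    nodal and edge betweenness are nonzero at every time index
    (``mode='all'``, the default) or at any one (``mode='any'``).
    Qualifying nodes are then pruned to a fixed point: a hub is
    retained only if, at some time index, it has a
    nonzero-edge-betweenness link to another retained hub in a
    different community.  (The retention rule is a property of the
    condition's hub set, so support is aggregated over time indices;
    requiring it independently at every time index would discard hubs
    whose intermodular edges rotate across time.)
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    if not metrics_by_time:
        raise ValueError("no time-point metrics supplied")
    n = next(iter(metrics_by_time.values())).metrics.participation.shape[0]
    verdicts = np.array(
        [[_passes_rule(m, v, pc_threshold) for v in range(n)]
         for m in metrics_by_time.values()]
    )
    passing = verdicts.all(axis=0) if mode == "all" else verdicts.any(axis=0)
    hubs = set(np.where(passing)[0])

    changed = True
    while changed:
        changed = False
        for v in sorted(hubs):
            supported = any(
                m.edge_bc[v, u] != 0
                and m.partition.assignment[u] != m.partition.assignment[v]
                for m in metrics_by_time.values()
                for u in hubs
                if u != v
            )
            if not supported:
                hubs.discard(v)
                changed = True

    records = {
        k: {
            int(v): (
                float(m.metrics.participation[v]),
                float(m.metrics.nodal_betweenness[v]),
                int(m.partition.assignment[v]),
            )
            for v in sorted(hubs)
        }
        for k, m in metrics_by_time.items()
    }
    return ConnectorHubSet(condition=condition,
                           hubs=tuple(sorted(int(v) for v in hubs)),
                           records=records)


def sparsify_by_edge_betweenness(
    edge_bc: np.ndarray,
    group_z: GroupConnectivityMatrix,
    hubs: ConnectorHubSet,
    time_index: int,
) -> ConnectorNetwork:
    """Mask the signed group matrix by binarized edge betweenness.

    Restricted to hub rows/columns: an edge (i, j) is present iff its
    edge betweenness in the full graph is nonzero, and it carries the
    (signed) Fisher-z group connectivity value unchanged.
    """
    z = group_z.z_values
    if edge_bc.shape != z.shape:
        raise ValueError("edge betweenness and group matrix indexing mismatch")
    nodes = hubs.hubs
    edges = [
        (i, j, float(z[i, j]))
        for a, i in enumerate(nodes)
        for j in nodes[a + 1:]
        if edge_bc[i, j] != 0
    ]
    communities = {v: rec[2] for v, rec in hubs.records.get(time_index, {}).items()}
    return ConnectorNetwork(condition=hubs.condition, time_index=time_index,
                            nodes=nodes, signed_edges=edges,
                            communities=communities)


def extract_backbone(
    networks: dict[tuple[str, int], ConnectorNetwork],
) -> FunctionalBackbone:
    """Hubs shared across all conditions and edges stable across time.

    ``shared_hubs`` is the intersection of the per-condition hub sets;
    ``stable_edges`` per condition is the intersection of edge sets
    over all time indices; ``condition_patterns`` binarizes the stable
    adjacency restricted to the shared hubs.
    """
    if not networks:
        raise ValueError("no connector networks supplied")
    by_condition: dict[str, list[ConnectorNetwork]] = {}
    for (cond, _), net in sorted(networks.items()):
        by_condition.setdefault(cond, []).append(net)

    hub_sets = {c: set(nets[0].nodes) for c, nets in by_condition.items()}
    shared = set.intersection(*hub_sets.values()) if hub_sets else set()
    shared_hubs = tuple(sorted(shared))

    stable_edges: dict[str, frozenset[tuple[int, int]]] = {}
    patterns: dict[str, np.ndarray] = {}
    idx = {v: k for k, v in enumerate(shared_hubs)}
    for cond, nets in by_condition.items():
        inter = frozenset.intersection(*[net.edge_set() for net in nets])
        stable_edges[cond] = inter
        a = np.zeros((len(shared_hubs), len(shared_hubs)), dtype=int)
        for i, j in inter:
            if i in idx and j in idx:
                a[idx[i], idx[j]] = a[idx[j], idx[i]] = 1
        patterns[cond] = a
    return FunctionalBackbone(shared_hubs=shared_hubs, stable_edges=stable_edges,
                              condition_patterns=patterns)


def intermodular_sign_summary(network: ConnectorNetwork) -> SignSummary:
    """Count and sign intermodular (cross-community) connector edges.

    Returns a declared-empty summary (fraction ``None``) when the
    network has no intermodular edge.
    """
    n_inter = n_neg = 0
    for i, j, value in network.signed_edges:
        ci = network.communities.get(i)
        cj = network.communities.get(j)
        if ci is None or cj is None or ci == cj:
            continue
        n_inter += 1
        if value < 0:
            n_neg += 1
    return SignSummary(condition=network.condition,
                       time_index=network.time_index,
                       n_intermodular=n_inter, n_negative=n_neg)
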
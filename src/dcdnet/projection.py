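"""One-mode projections, connected-component modules and hub statistics.

Projecting the drug-disease network onto one side links two same-role
nodes whenever they share a neighbor; the edge weight sums, over shared
neighbors, the minimum of the two incident bipartite weights.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from dcdnet.io_tables import EntityId, iter_weighted_edges


def _pair(u: EntityId, v: EntityId) -> tuple[EntityId, EntityId]:
    return (u, v) if u.token <= v.token else (v, u)


@dataclass
class ProjectedGraph:
    """Weighted graph over a single node role (drug-drug or disease-disease)."""

    role: str
    edges: dict[tuple[EntityId, EntityId], float] = field(default_factory=dict)
    _adj: dict[EntityId, dict[EntityId, float]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        canonical: dict[tuple[EntityId, EntityId], float] = {}
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on {u.token!r}")
            if w <= 0.0:
                raise ValueError(f"edge ({u.token}, {v.token}) weight {w} must be > 0")
            canonical[_pair(u, v)] = w
        self.edges = canonical

    def _adjacency(self) -> dict[EntityId, dict[EntityId, float]]:
        if self._adj is None:
            adj: dict[EntityId, dict[EntityId, float]] = {}
            for (u, v), w in self.edges.items():
                adj.setdefault(u, {})[v] = w
                adj.setdefault(v, {})[u] = w
            object.__setattr__(self, "_adj", adj)
        return self._adj  # type: ignore[return-value]

    def nodes(self) -> frozenset[EntityId]:
        return frozenset(self._adjacency())

    def neighbors(self, node: EntityId) -> dict[EntityId, float]:
        return dict(self._adjacency().get(node, {}))

    def weight(self, u: EntityId, v: EntityId) -> float:
        return self.edges.get(_pair(u, v), 0.0)

    def strength(self, node: EntityId) -> float:
        """Weighted degree: sum of incident edge weights."""
        return sum(self._adjacency().get(node, {}).values())

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def iter_edges(self) -> Iterator[tuple[EntityId, EntityId, float]]:
        for (u, v), w in self.edges.items():
            yield u, v, w


def project(bipartite, side: str) -> ProjectedGraph:
    """One-mode projection of a weighted bipartite graph.

    ``side`` selects which endpoint role becomes the node set ("drug"
    projects onto first-column nodes, "disease" onto second-column ones).
    w(u, u') = sum over shared neighbors s of min(w(u, s), w(u', s)); the
    sum runs only over the neighborhood intersection since a missing edge
    contributes zero.
    """
    if side not in ("drug", "disease"):
        raise ValueError(f"side must be 'drug' or 'disease', got {side!r}")
    adj: dict[EntityId, dict[EntityId, float]] = {}
    for t, d, w in bipartite.iter_edges():
        u, s = (t, d) if side == "drug" else (d, t)
        adj.setdefault(s, {})  # ensure shared-neighbor index below sees s
        adj.setdefault(u, {})[s] = w

    by_shared: dict[EntityId, list[EntityId]] = {}
    for u, nbrs in adj.items():
        for s in nbrs:
            by_shared.setdefault(s, []).append(u)

    # accumulate in sorted shared-neighbor order so sums are reproducible
    # and bitwise-identical to a sorted reference loop
    edges: dict[tuple[EntityId, EntityId], float] = {}
    for s in sorted(by_shared, key=lambda e: e.token):
        members = by_shared[s]
        members = sorted(members, key=lambda e: e.token)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                u, v = members[i], members[j]
                key = _pair(u, v)
                edges[key] = edges.get(key, 0.0) + min(adj[u][s], adj[v][s])
    return ProjectedGraph(role=side, edges=edges)


def _as_nx(graph) -> nx.Graph:
    g = nx.Graph()
    for u, v, w in iter_weighted_edges(graph):
        g.add_edge(u, v, weight=w)
    return g


def connected_components(graph) -> list[frozenset[str]]:
    """Maximal connected node sets (non-isolated nodes only).

    Accepts any weighted graph object (derived bipartite or projection).
    Sorted by size descending, then by lexicographic smallest member.
    """
    comps = [frozenset(c) for c in nx.connected_components(_as_nx(graph))]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def hub_statistics(bipartite) -> pd.DataFrame:
    """Per-node degree and weighted degree (sum of incident edge weights).

    Returns a frame with columns node, side, degree, weighted_degree,
    sorted by weighted degree descending then node. ``side`` is "left" or
    "right" according to the column the node appeared in.
    """
    degree: dict[str, int] = {}
    strength: dict[str, float] = {}
    side: dict[str, str] = {}
    for u, v, w in iter_weighted_edges(bipartite):
        for node, s in ((u, "left"), (v, "right")):
            degree[node] = degree.get(node, 0) + 1
            strength[node] = strength.get(node, 0.0) + w
            side.setdefault(node, s)
    frame = pd.DataFrame(
        {
            "node": list(degree),
            "side": [side[n] for n in degree],
            "degree": [degree[n] for n in degree],
            "weighted_degree": [strength[n] for n in degree],
        }
    )
    return frame.sort_values(
        ["weighted_degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)
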
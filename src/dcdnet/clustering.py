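"""Greedy overlapping module detection on weighted graphs.

Reimplements the cohesiveness-growth clustering scheme popularised by
ClusterONE: grow candidate groups from high-strength seeds by single-node
additions/removals that increase

    cohesiveness(S) = W_in / (W_in + W_bound + penalty * |S|),

merge heavily overlapping groups, and keep those meeting minimum size and
weighted density. Seed order and all tie-breaks are fixed so the output is
deterministic for a given input and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

from dcdnet.io_tables import EntityId
from dcdnet.projection import ProjectedGraph
from dcdnet.tripartite import overlap_weight

_EPS = 1e-12


@dataclass(frozen=True)
class Cluster:
    """A detected module with its quality scores."""

    members: frozenset[EntityId]
    cohesiveness: float
    density: float

    def __len__(self) -> int:
        return len(self.members)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(sorted(m.token for m in self.members))


def _in_bound(graph: ProjectedGraph, nodes: frozenset[EntityId]) -> tuple[float, float]:
    w_in = 0.0
    w_bound = 0.0
    for (u, v), w in graph.edges.items():
        inside = (u in nodes) + (v in nodes)
        if inside == 2:
            w_in += w
        elif inside == 1:
            w_bound += w
    return w_in, w_bound


def cohesiveness(graph: ProjectedGraph, nodes, penalty: float = 0.0) -> float:
    """W_in / (W_in + W_bound + penalty * |nodes|)."""
    nodes = frozenset(nodes)
    if not nodes:
        raise ValueError("cohesiveness is undefined for the empty set")
    if not nodes <= graph.nodes():
        unknown = sorted(n.token for n in nodes - graph.nodes())
        raise ValueError(f"nodes not in graph: {unknown}")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    w_in, w_bound = _in_bound(graph, nodes)
    denom = w_in + w_bound + penalty * len(nodes)
    return w_in / denom if denom > 0 else 0.0


def weighted_density(graph: ProjectedGraph, nodes) -> float:
    """Sum of internal edge weights over the number of possible node pairs."""
    nodes = frozenset(nodes)
    if len(nodes) < 2:
        raise ValueError("weighted_density needs at least 2 nodes")
    w_in, _ = _in_bound(graph, nodes)
    n = len(nodes)
    return w_in / (n * (n - 1) / 2)


def _grow(graph: ProjectedGraph, seed: EntityId, penalty: float) -> frozenset[EntityId]:
    """Greedy single-node growth/shrink from a seed, maximizing cohesiveness."""
    cur: set[EntityId] = {seed}
    w_in = 0.0
    w_bound = graph.strength(seed)

    def score(win: float, wbound: float, size: int) -> float:
        denom = win + wbound + penalty * size
        return win / denom if denom > 0 else 0.0

    def better(cand: tuple[float, int, str], best: tuple[float, int, str] | None) -> bool:
        # higher score wins; ties prefer additions (op-rank 0), then lexicographic
        if best is None:
            return True
        if cand[0] > best[0] + _EPS:
            return True
        return abs(cand[0] - best[0]) <= _EPS and (cand[1], cand[2]) < (best[1], best[2])

    current = score(w_in, w_bound, 1)
    while True:
        boundary: dict[EntityId, float] = {}
        for u in cur:
            for v, w in graph.neighbors(u).items():
                if v not in cur:
                    boundary[v] = boundary.get(v, 0.0) + w

        best: tuple[float, int, str] | None = None
        best_node: EntityId | None = None
        for v, w_to_in in boundary.items():
            s = score(
                w_in + w_to_in,
                w_bound - w_to_in + (graph.strength(v) - w_to_in),
                len(cur) + 1,
            )
            cand = (s, 0, v.token)
            if better(cand, best):
                best, best_node = cand, v
        if len(cur) > 1:
            for u in cur:
                w_to_in = sum(w for v, w in graph.neighbors(u).items() if v in cur)
                s = score(
                    w_in - w_to_in,
                    w_bound - (graph.strength(u) - w_to_in) + w_to_in,
                    len(cur) - 1,
                )
                cand = (s, 1, u.token)
                if better(cand, best):
                    best, best_node = cand, u

        if best is None or best_node is None or best[0] <= current + _EPS:
            return frozenset(cur)
        node = best_node
        if best[1] == 0:  # add
            w_to_in = boundary[node]
            w_in += w_to_in
            w_bound += graph.strength(node) - 2 * w_to_in
            cur.add(node)
        else:  # remove
            w_to_in = sum(w for v, w in graph.neighbors(node).items() if v in cur)
            w_in -= w_to_in
            w_bound += 2 * w_to_in - graph.strength(node)
            cur.remove(node)
        current = best[0]


def _merge_overlapping(
    groups: list[frozenset[EntityId]], overlap_threshold: float
) -> list[frozenset[EntityId]]:
    groups = sorted(set(groups), key=lambda g: (min(m.token for m in g), -len(g)))
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                if overlap_weight(a, b) >= overlap_threshold:
                    groups[i] = a | b
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
        if merged:
            groups.sort(key=lambda g: (min(m.token for m in g), -len(g)))
    return groups


def cluster_graph(
    graph: ProjectedGraph,
    min_density: float = 0.35,
    min_size: int = 3,
    overlap_threshold: float = 0.8,
    penalty: float = 2.0,
) -> list[Cluster]:
    """Detect overlapping modules by greedy cohesiveness growth.

    Seeds are the not-yet-clustered nodes in decreasing weighted-degree
    order (ties broken lexicographically); grown groups whose pairwise set
    overlap |A∩B|²/(|A|·|B|) reaches ``overlap_threshold`` are merged;
    groups smaller than ``min_size`` or sparser than ``min_density`` are
    discarded. Output is sorted by size descending then smallest member.
    """
    if not (0.0 <= min_density <= 1.0):
        raise ValueError("min_density must be in [0, 1]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not (0.0 < overlap_threshold <= 1.0):
        raise ValueError("overlap_threshold must be in (0, 1]")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")

    order = sorted(graph.nodes(), key=lambda n: (-graph.strength(n), n.token))
    clustered: set[EntityId] = set()
    groups: list[frozenset[EntityId]] = []
    for seed in order:
        if seed in clustered:
            continue
        grown = _grow(graph, seed, penalty)
        groups.append(grown)
        clustered.update(grown)

    groups = _merge_overlapping(groups, overlap_threshold)

    clusters = []
    for g in groups:
        if len(g) < min_size:
            continue
        density = weighted_density(graph, g)
        if density < min_density:
            continue
        clusters.append(
            Cluster(members=g, cohesiveness=cohesiveness(graph, g, penalty), density=density)
        )
    clusters.sort(key=lambda c: (-len(c.members), c.tokens))
    return clusters
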
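"""Weighted tripartite network construction.

The drug-complex and complex-disease layers are weighted by the symmetric
conditional probability of the two gene sets: for sets A and B the edge
weight is |A∩B|² / (|A|·|B|), the product of the two conditional overlap
probabilities. An edge exists exactly when the sets intersect, so every
stored weight lies in (0, 1].
"""

from __future__ import annotations

import logging
from collections.abc import Iterator, Set as AbstractSet
from dataclasses import dataclass, field

from dcdnet.io_tables import EntityId, GeneSetMap

logger = logging.getLogger(__name__)


def overlap_weight(set_a: AbstractSet, set_b: AbstractSet) -> float:
    """Symmetric conditional probability weight |A∩B|²/(|A|·|B|).

    Symmetric, in [0, 1]; 1 iff the sets are equal, 0 iff disjoint.
    Raises ``ValueError`` on an empty operand (undefined denominator).
    """
    if not set_a or not set_b:
        raise ValueError("overlap_weight is undefined for empty sets")
    shared = len(set_a & set_b)
    return (shared * shared) / (len(set_a) * len(set_b))


@dataclass
class WeightedBipartiteGraph:
    """Weighted edges between two disjoint entity roles.

    Only edges with weight in (0, 1] are stored; absence of an edge means
    zero overlap.
    """

    left_role: str
    right_role: str
    edges: dict[tuple[EntityId, EntityId], float] = field(default_factory=dict)
    _left_adj: dict[EntityId, dict[EntityId, float]] | None = field(
        default=None, repr=False, compare=False
    )
    _right_adj: dict[EntityId, dict[EntityId, float]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.left_role == self.right_role:
            raise ValueError("left and right roles must differ")
        for (left, right), w in self.edges.items():
            if left.role != self.left_role or right.role != self.right_role:
                raise ValueError(
                    f"edge ({left.token}, {right.token}) violates roles "
                    f"({self.left_role}, {self.right_role})"
                )
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge ({left.token}, {right.token}) weight {w} not in (0, 1]")

    def _adjacency(self) -> tuple[dict, dict]:
        if self._left_adj is None or self._right_adj is None:
            left_adj: dict[EntityId, dict[EntityId, float]] = {}
            right_adj: dict[EntityId, dict[EntityId, float]] = {}
            for (left, right), w in self.edges.items():
                left_adj.setdefault(left, {})[right] = w
                right_adj.setdefault(right, {})[left] = w
            object.__setattr__(self, "_left_adj", left_adj)
            object.__setattr__(self, "_right_adj", right_adj)
        return self._left_adj, self._right_adj  # type: ignore[return-value]

    def weight(self, left: EntityId, right: EntityId) -> float:
        """Edge weight, 0.0 when absent."""
        return self.edges.get((left, right), 0.0)

    def left_neighbors(self, left: EntityId) -> dict[EntityId, float]:
        return dict(self._adjacency()[0].get(left, {}))

    def right_neighbors(self, right: EntityId) -> dict[EntityId, float]:
        return dict(self._adjacency()[1].get(right, {}))

    def left_strength(self, left: EntityId) -> float:
        """Sum of incident edge weights of a left node."""
        return sum(self._adjacency()[0].get(left, {}).values())

    def right_strength(self, right: EntityId) -> float:
        return sum(self._adjacency()[1].get(right, {}).values())

    def connected_left(self) -> frozenset[EntityId]:
        """Left nodes incident to >= 1 edge (the reporting convention)."""
        return frozenset(self._adjacency()[0])

    def connected_right(self) -> frozenset[EntityId]:
        return frozenset(self._adjacency()[1])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def iter_edges(self) -> Iterator[tuple[EntityId, EntityId, float]]:
        for (left, right), w in self.edges.items():
            yield left, right, w


def build_bipartite(left: GeneSetMap, right: GeneSetMap) -> WeightedBipartiteGraph:
    """Weight every intersecting (left, right) entity pair by overlap_weight.

    Candidate pairs are found through a gene -> entity inverted index so
    disjoint pairs are never touched; isolated entities simply carry no
    edges.
    """
    if left.role == right.role:
        raise ValueError("left and right gene-set maps must have different roles")
    index: dict[EntityId, list[EntityId]] = {}
    for r_entity, genes in right.entries.items():
        for g in genes:
            index.setdefault(g, []).append(r_entity)

    edges: dict[tuple[EntityId, EntityId], float] = {}
    for l_entity, l_genes in left.entries.items():
        candidates: set[EntityId] = set()
        for g in l_genes:
            candidates.update(index.get(g, ()))
        for r_entity in candidates:
            w = overlap_weight(l_genes, right.entries[r_entity])
            if w > 0.0:
                edges[(l_entity, r_entity)] = w
    graph = WeightedBipartiteGraph(left_role=left.role, right_role=right.role, edges=edges)
    logger.info(
        "built %s-%s layer: %d connected %ss, %d connected %ss, %d edges",
        left.role, right.role, len(graph.connected_left()), left.role,
        len(graph.connected_right()), right.role, graph.n_edges,
    )
    return graph


@dataclass
class TripartiteNetwork:
    """Two weighted bipartite layers sharing the complex node set."""

    drugs: GeneSetMap
    complexes: GeneSetMap
    diseases: GeneSetMap
    drug_complex: WeightedBipartiteGraph
    complex_disease: WeightedBipartiteGraph

    def __post_init__(self) -> None:
        if (self.drugs.role, self.complexes.role, self.diseases.role) != (
            "drug", "complex", "disease",
        ):
            raise ValueError("gene-set maps must have roles drug/complex/disease")
        for left, _right in self.drug_complex.edges:
            if left not in self.drugs:
                raise ValueError(f"drug {left.token!r} missing from gene-set map")
        for _left, right in self.complex_disease.edges:
            if right not in self.diseases:
                raise ValueError(f"disease {right.token!r} missing from gene-set map")


def build_tripartite(
    drugs: GeneSetMap, complexes: GeneSetMap, diseases: GeneSetMap
) -> TripartiteNetwork:
    """Assemble the drug-complex-disease tripartite network."""
    if (drugs.role, complexes.role, diseases.role) != ("drug", "complex", "disease"):
        raise ValueError(
            "expected gene-set maps with roles drug, complex, disease (in that order)"
        )
    return TripartiteNetwork(
        drugs=drugs.drop_empty(),
        complexes=complexes.drop_empty(),
        diseases=diseases.drop_empty(),
        drug_complex=build_bipartite(drugs, complexes),
        complex_disease=build_bipartite(complexes, diseases),
    )
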
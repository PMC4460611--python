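"""Derive the weighted drug-disease bipartite network from the tripartite one.

A drug t and a disease d are linked whenever they share at least one
complex neighbor; the edge weight is

    w(t, d) = (g_T(t, C) / g(t)) * (g_D(d, C) / g(d))

where C is the set of shared complex neighbors, g_T(t, C) / g_D(d, C) sum
the layer weights from t / d into C, and g(t) / g(d) sum over all complex
neighbors. Pairs with no shared complex but directly overlapping gene sets
fall back to the plain set-overlap weight; those edges carry provenance
``direct_fallback`` and empty support so downstream filters can treat them
separately.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from dcdnet.io_tables import EntityId, GeneSetMap
from dcdnet.tripartite import TripartiteNetwork, overlap_weight

Provenance = Literal["via_complexes", "direct_fallback"]


@dataclass(frozen=True)
class DerivedEdge:
    """One candidate drug-disease association with its supporting complexes."""

    drug: EntityId
    disease: EntityId
    weight: float
    provenance: Provenance
    support: frozenset[EntityId] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0 + 1e-12):
            raise ValueError(f"derived weight {self.weight} not in (0, 1]")
        if self.provenance == "via_complexes" and not self.support:
            raise ValueError("via_complexes edge requires non-empty support")
        if self.provenance == "direct_fallback" and self.support:
            raise ValueError("direct_fallback edge must have empty support")


@dataclass
class DerivedBipartite:
    """The weighted drug-disease network with per-edge provenance."""

    edges: dict[tuple[EntityId, EntityId], DerivedEdge] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drugs(self) -> frozenset[EntityId]:
        return frozenset(t for t, _ in self.edges)

    def diseases(self) -> frozenset[EntityId]:
        return frozenset(d for _, d in self.edges)

    def weight(self, drug: EntityId, disease: EntityId) -> float:
        edge = self.edges.get((drug, disease))
        return edge.weight if edge is not None else 0.0

    def iter_edges(self) -> Iterator[tuple[EntityId, EntityId, float]]:
        for (t, d), edge in self.edges.items():
            yield t, d, edge.weight

    def restrict_to_disease(self, disease: EntityId | str) -> "DerivedBipartite":
        """Sub-network of edges incident to one disease (case-folded match)."""
        key = disease.token if isinstance(disease, EntityId) else disease
        key = key.strip().casefold()
        kept = {
            pair: edge
            for pair, edge in self.edges.items()
            if pair[1].token.strip().casefold() == key
        }
        if not kept and not any(
            d.token.strip().casefold() == key for _, d in self.edges
        ):
            raise LookupError(f"unknown disease {key!r}")
        return DerivedBipartite(edges=kept, metadata=dict(self.metadata))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": t.token,
                "disease": d.token,
                "weight": edge.weight,
                "provenance": edge.provenance,
                "support": ",".join(sorted(c.token for c in edge.support)),
            }
            for (t, d), edge in self.edges.items()
        ]
        frame = pd.DataFrame(rows, columns=["drug", "disease", "weight", "provenance", "support"])
        return frame.sort_values(
            ["weight", "drug", "disease"], ascending=[False, True, True]
        ).reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "DerivedBipartite":
        edges: dict[tuple[EntityId, EntityId], DerivedEdge] = {}
        for row in frame.itertuples(index=False):
            drug = EntityId("drug", str(row.drug))
            disease = EntityId("disease", str(row.disease))
            provenance = getattr(row, "provenance", "via_complexes")
            support_field = str(getattr(row, "support", "") or "")
            support = frozenset(
                EntityId("complex", tok) for tok in support_field.split(",") if tok.strip()
            )
            edges[(drug, disease)] = DerivedEdge(
                drug=drug,
                disease=disease,
                weight=float(row.weight),
                provenance=provenance,
                support=support,
            )
        return cls(edges=edges, metadata=metadata or {})

    def write_tsv(self, path, precision: int | None = None) -> None:
        """Edge table with provenance and comma-joined support columns."""
        frame = self.to_frame()
        if precision is not None:
            frame["weight"] = frame["weight"].map(lambda w: f"{w:.{precision}f}")
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "DerivedBipartite":
        frame = pd.read_csv(
            path, sep="\t", dtype={"drug": str, "disease": str, "support": str},
            keep_default_na=False,
        )
        return cls.from_frame(frame)


def common_complexes(
    t: EntityId, d: EntityId, net: TripartiteNetwork
) -> frozenset[EntityId]:
    """Complexes adjacent to both the drug and the disease; may be empty."""
    if t not in net.drugs:
        raise LookupError(f"unknown drug {t.token!r}")
    if d not in net.diseases:
        raise LookupError(f"unknown disease {d.token!r}")
    drug_side = net.drug_complex.left_neighbors(t)
    disease_side = net.complex_disease.right_neighbors(d)
    return frozenset(drug_side) & frozenset(disease_side)


def derived_weight(
    t: EntityId,
    d: EntityId,
    net: TripartiteNetwork,
    support: frozenset[EntityId] | None = None,
) -> float:
    """Shared-complex association weight (g_T(t,C)/g(t)) * (g_D(d,C)/g(d)).

    The denominators run over all complex neighbors, which equals the sum
    over the full complex universe because absent edges weigh zero.
    """
    if support is None:
        support = common_complexes(t, d, net)
    if not support:
        raise ValueError(f"({t.token}, {d.token}) share no complex; use the fallback rule")
    drug_side = net.drug_complex.left_neighbors(t)
    disease_side = net.complex_disease.right_neighbors(d)
    g_t_c = sum(drug_side[p] for p in support)
    g_d_c = sum(disease_side[p] for p in support)
    g_t = sum(drug_side.values())
    g_d = sum(disease_side.values())
    return (g_t_c / g_t) * (g_d_c / g_d)


def fallback_weight(
    t: EntityId, d: EntityId, drugs: GeneSetMap, diseases: GeneSetMap
) -> float:
    """Direct target/disease-gene overlap weight for complex-disconnected pairs."""
    targets = drugs.genes(t)
    genes = diseases.genes(d)
    w = overlap_weight(targets, genes)
    if w == 0.0:
        raise ValueError(f"({t.token}, {d.token}) share no gene; no edge exists")
    return w


def derive_drug_disease(net: TripartiteNetwork) -> DerivedBipartite:
    """Build the full candidate drug-disease network.

    Every pair with shared complex neighbors gets a ``via_complexes`` edge;
    pairs without any shared complex but with directly overlapping gene
    sets get a ``direct_fallback`` edge; all other pairs stay unlinked.
    """
    edges: dict[tuple[EntityId, EntityId], DerivedEdge] = {}

    # via-complex edges: reachable diseases only, through the complex layer
    for t in net.drugs:
        drug_side = net.drug_complex.left_neighbors(t)
        if not drug_side:
            continue
        reachable: dict[EntityId, set[EntityId]] = {}
        for p in drug_side:
            for d in net.complex_disease.left_neighbors(p):
                reachable.setdefault(d, set()).add(p)
        for d, support_set in reachable.items():
            support = frozenset(support_set)
            w = derived_weight(t, d, net, support=support)
            edges[(t, d)] = DerivedEdge(
                drug=t, disease=d, weight=min(w, 1.0),
                provenance="via_complexes", support=support,
            )

    # fallback edges: direct gene overlap for complex-disconnected pairs
    gene_index: dict[EntityId, list[EntityId]] = {}
    for d, genes in net.diseases.entries.items():
        for g in genes:
            gene_index.setdefault(g, []).append(d)
    for t, targets in net.drugs.entries.items():
        candidates: set[EntityId] = set()
        for g in targets:
            candidates.update(gene_index.get(g, ()))
        for d in candidates:
            if (t, d) in edges:
                continue
            w = overlap_weight(targets, net.diseases.entries[d])
            edges[(t, d)] = DerivedEdge(
                drug=t, disease=d, weight=w, provenance="direct_fallback",
            )

    n_via = sum(1 for e in edges.values() if e.provenance == "via_complexes")
    return DerivedBipartite(
        edges=edges,
        metadata={
            "n_edges": len(edges),
            "n_via_complexes": n_via,
            "n_direct_fallback": len(edges) - n_via,
            "n_drugs": len({t for t, _ in edges}),
            "n_diseases": len({d for _, d in edges}),
        },
    )
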
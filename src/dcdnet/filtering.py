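"""PPI-support and weight-threshold filtering of candidate associations.

A shared-complex association is kept only if, inside at least one
supporting complex, a drug target and a disease gene interact directly in
the binary PPI network. When one gene is simultaneously a drug target and
a disease gene within a supporting complex the association is kept without
a PPI edge (disable with ``strict_distinct_genes``). Fallback-provenance
edges have no supporting complex, so the PPI test does not apply to them;
they are retained (subject to the weight threshold) unless dropped
explicitly.

The weight threshold is inclusive: ``weight >= min_weight`` survives.
"""

from __future__ import annotations

import logging

from dcdnet.derivation import DerivedBipartite, DerivedEdge
from dcdnet.io_tables import PPINetwork
from dcdnet.tripartite import TripartiteNetwork

logger = logging.getLogger(__name__)


def ppi_supported(
    edge: DerivedEdge,
    net: TripartiteNetwork,
    ppi: PPINetwork,
    *,
    allow_shared_gene: bool = True,
) -> bool:
    """True iff some supporting complex links the pair through the PPI network.

    Looks for a drug target g1 and a disease gene g2, both subunits of one
    supporting complex, with g1 != g2 and a direct PPI edge between them;
    or (by default) a single gene that is both a target and a disease gene
    in that complex.
    """
    if edge.provenance != "via_complexes":
        raise ValueError("ppi_supported applies only to via_complexes edges")
    targets = net.drugs.genes(edge.drug)
    disease_genes = net.diseases.genes(edge.disease)
    for complex_id in edge.support:
        subunits = net.complexes.genes(complex_id)
        t_genes = targets & subunits
        d_genes = disease_genes & subunits
        if not t_genes or not d_genes:
            continue
        if allow_shared_gene and (t_genes & d_genes):
            return True
        for g1 in t_genes:
            for g2 in d_genes:
                if g1 != g2 and ppi.has_edge(g1, g2):
                    return True
    return False


def filter_network(
    derived: DerivedBipartite,
    net: TripartiteNetwork,
    ppi: PPINetwork,
    min_weight: float = 0.5,
    *,
    keep_fallback: bool = True,
    strict_distinct_genes: bool = False,
) -> DerivedBipartite:
    """Apply the PPI-support filter, then the inclusive weight threshold.

    Stage-by-stage edge counts are recorded in the result's metadata.
    """
    if not (0.0 <= min_weight <= 1.0):
        raise ValueError(f"min_weight {min_weight} not in [0, 1]")

    after_ppi: dict = {}
    for pair, edge in derived.edges.items():
        if edge.provenance == "via_complexes":
            if ppi_supported(edge, net, ppi, allow_shared_gene=not strict_distinct_genes):
                after_ppi[pair] = edge
        elif keep_fallback:
            after_ppi[pair] = edge

    kept = {pair: e for pair, e in after_ppi.items() if e.weight >= min_weight}

    counts = {
        "n_input": derived.n_edges,
        "n_after_ppi": len(after_ppi),
        "n_after_threshold": len(kept),
        "min_weight": min_weight,
        "n_drugs": len({t for t, _ in kept}),
        "n_diseases": len({d for _, d in kept}),
    }
    logger.info(
        "filter: %d edges in, %d after PPI support, %d after weight >= %.2f",
        counts["n_input"], counts["n_after_ppi"], counts["n_after_threshold"], min_weight,
    )
    return DerivedBipartite(edges=kept, metadata={**derived.metadata, "filter": counts})
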
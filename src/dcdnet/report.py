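"""Ranked association tables, benchmark annotation and weight histograms."""

from __future__ import annotations

import numpy as np
import pandas as pd

from dcdnet.derivation import DerivedBipartite
from dcdnet.io_tables import EntityId, KnownAssociationTable


def rank_associations(
    derived: DerivedBipartite,
    disease: EntityId | str | None = None,
    *,
    drug_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank candidate associations by weight descending (ties: drug token).

    With ``disease`` given, restrict the table to that single disease
    (case-folded name match; unknown name raises ``LookupError``). An
    optional ``drug_names`` mapping adds a human-readable drug_name column.
    """
    network = derived if disease is None else derived.restrict_to_disease(disease)
    rows = [
        {
            "drug": t.token,
            "disease": d.token,
            "weight": edge.weight,
            "provenance": edge.provenance,
        }
        for (t, d), edge in network.edges.items()
    ]
    frame = pd.DataFrame(rows, columns=["drug", "disease", "weight", "provenance"])
    frame = frame.sort_values(
        ["weight", "drug", "disease"], ascending=[False, True, True]
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    if drug_names is not None:
        frame.insert(2, "drug_name", frame["drug"].map(lambda t: drug_names.get(t, "")))
    return frame


def annotate_with_benchmark(
    ranked: pd.DataFrame, known: KnownAssociationTable
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label each row known/novel by benchmark membership; return counts.

    Disease names are matched case-insensitively. The association
    direction (therapeutic vs adverse) is not resolved; rows only say
    whether the pair appears in the benchmark at all.
    """
    annotated = ranked.copy()
    annotated["benchmark"] = [
        "known" if known.contains(str(row.drug), str(row.disease)) else "novel"
        for row in ranked.itertuples(index=False)
    ]
    n_known = int((annotated["benchmark"] == "known").sum())
    summary = {"known": n_known, "novel": len(annotated) - n_known, "total": len(annotated)}
    return annotated, summary


def weight_histogram(candidates, breakpoints: list[float]) -> pd.DataFrame:
    """Fraction of edge weights per half-open bin [b_i, b_{i+1}).

    ``breakpoints`` are interior cut points, sorted ascending within
    [0, 1]; the bins are [0, b_1), [b_1, b_2), ..., [b_k, 1]. Accepts a
    derived network or any weighted-edge iterable. Fractions sum to 1.
    """
    bps = list(breakpoints)
    if any(not (0.0 <= b <= 1.0) for b in bps):
        raise ValueError("breakpoints must lie in [0, 1]")
    if bps != sorted(bps) or len(set(bps)) != len(bps):
        raise ValueError("breakpoints must be strictly ascending")
    if isinstance(candidates, DerivedBipartite):
        weights = np.array([e.weight for e in candidates.edges.values()])
    else:
        from dcdnet.io_tables import iter_weighted_edges

        weights = np.array([w for _, _, w in iter_weighted_edges(candidates)])
    edges = np.array([0.0, *bps, np.inf])
    counts, _ = np.histogram(weights, bins=edges)
    fractions = counts / len(weights) if len(weights) else counts.astype(float)
    labels = [
        f"[{edges[i]:g}, {edges[i + 1]:g})" if np.isfinite(edges[i + 1]) else f"[{edges[i]:g}, 1]"
        for i in range(len(edges) - 1)
    ]
    return pd.DataFrame({"bin": labels, "count": counts, "fraction": fractions})
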
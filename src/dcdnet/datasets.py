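"""Small curated tables distributed with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from dcdnet.io_tables import EntityId
from dcdnet.tripartite import WeightedBipartiteGraph


def load_mental_disorders_associations() -> tuple[WeightedBipartiteGraph, dict[str, str]]:
    """Published high-confidence drug associations for the mental-disorders node.

    Returns the weighted drug-disease star (51 edges, weights at two
    decimals as published) and a drug-id -> drug-name mapping.
    """
    with resources.files("dcdnet.data").joinpath(
        "mental_disorders_associations.tsv"
    ).open("r", encoding="utf-8") as handle:
        frame = pd.read_csv(handle, sep="\t", dtype={"drug": str, "drug_name": str})
    edges = {
        (EntityId("drug", row.drug), EntityId("disease", row.disease)): float(row.weight)
        for row in frame.itertuples(index=False)
    }
    names = dict(zip(frame["drug"], frame["drug_name"]))
    return WeightedBipartiteGraph(left_role="drug", right_role="disease", edges=edges), names
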
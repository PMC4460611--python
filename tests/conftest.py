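from __future__ import annotations

import numpy as np
import pytest

from dcdnet.io_tables import EntityId, GeneSetMap


def eid(role: str, token: str) -> EntityId:
    return EntityId(role, token)


@pytest.fixture
def worked_tripartite():
    """The hand-worked example: one drug, three complexes, one disease.

    drug targets {1,2}; complexes p1={1,3}, p2={2,4,5}, p3={1,6,7,8};
    disease genes {3,4}. p1 and p2 bridge the pair, p3 touches only the
    drug.
    """
    from dcdnet.tripartite import build_tripartite

    drugs = GeneSetMap.from_dict("drug", {"t": [1, 2]})
    complexes = GeneSetMap.from_dict(
        "complex", {"p1": [1, 3], "p2": [2, 4, 5], "p3": [1, 6, 7, 8]}
    )
    diseases = GeneSetMap.from_dict("disease", {"d": [3, 4]})
    return build_tripartite(drugs, complexes, diseases)


def random_gene_set_map(rng: np.random.Generator, role: str, n_entities: int,
                        universe: int = 30, max_size: int = 8) -> GeneSetMap:
    entries = {}
    for i in range(n_entities):
        size = int(rng.integers(1, max_size + 1))
        genes = rng.choice(universe, size=size, replace=False) + 1
        entries[f"{role[0]}{i}"] = [int(g) for g in genes]
    return GeneSetMap.from_dict(role, entries)


def random_tripartite(rng: np.random.Generator, max_per_side: int = 15):
    """Random small tripartite network over a shared gene universe."""
    from dcdnet.tripartite import build_tripartite

    n_t = int(rng.integers(1, max_per_side + 1))
    n_p = int(rng.integers(1, max_per_side + 1))
    n_d = int(rng.integers(1, max_per_side + 1))
    drugs = random_gene_set_map(rng, "drug", n_t)
    complexes = random_gene_set_map(rng, "complex", n_p)
    diseases = random_gene_set_map(rng, "disease", n_d)
    return build_tripartite(drugs, complexes, diseases)
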
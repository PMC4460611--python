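"""Seeded synthetic inputs with planted drug-disease associations.

The generator emulates the statistical shape of drug-target,
complex-subunit and disease-gene tables plus a binary PPI network. Planted
(drug, disease) pairs are wired through dedicated complexes with two
distinct, PPI-connected genes each, so they survive the PPI-support filter
by construction; everything else overlaps only at a configurable
background rate.

Gene pools for complexes, drug-only targets and disease-only genes are
disjoint, and complex subunit sets are pairwise disjoint. With
``background_overlap_prob = 0`` this makes the planted pairs the *only*
possible drug-disease edges, which the test suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from dcdnet.io_tables import EntityId, GeneSetMap, PPINetwork
from dcdnet.projection import ProjectedGraph


@dataclass(frozen=True)
class FixtureParams:
    """Knobs for :func:`generate_fixture`; defaults give a small testbed."""

    n_drugs: int = 20
    n_complexes: int = 15
    n_diseases: int = 10
    gene_universe_size: int = 400
    drug_set_size: tuple[int, int] = (2, 6)
    complex_set_size: tuple[int, int] = (3, 8)
    disease_set_size: tuple[int, int] = (3, 10)
    n_planted_pairs: int = 5
    planted_overlap: int = 2
    background_overlap_prob: float = 0.02
    ppi_intra_complex_prob: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_complexes", "n_diseases", "gene_universe_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("drug_set_size", "complex_set_size", "disease_set_size"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= self.gene_universe_size):
                raise ValueError(f"{name} {lo, hi} out of range")
        for name in ("background_overlap_prob", "ppi_intra_complex_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_planted_pairs < 0 or self.planted_overlap < 0:
            raise ValueError("planted counts must be >= 0")
        if self.n_planted_pairs > min(self.n_drugs, self.n_diseases):
            raise ValueError("n_planted_pairs exceeds available drugs/diseases")
        if self.n_planted_pairs * self.planted_overlap > self.n_complexes:
            raise ValueError(
                "planted pairs need disjoint dedicated complexes: "
                "n_planted_pairs * planted_overlap must be <= n_complexes"
            )
        if self.n_planted_pairs and self.planted_overlap and self.complex_set_size[0] < 2:
            raise ValueError("planting needs complexes of size >= 2")


@dataclass
class Fixture:
    """Generated tables plus the planted ground truth."""

    drugs: GeneSetMap
    complexes: GeneSetMap
    diseases: GeneSetMap
    ppi: PPINetwork
    truth: list[tuple[EntityId, EntityId]]
    params: FixtureParams = field(default_factory=FixtureParams)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write the four canonical TSVs plus truth.tsv; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, gsm in (
            ("drugs", self.drugs), ("complexes", self.complexes), ("diseases", self.diseases),
        ):
            path = out / f"{name}.tsv"
            with open(path, "w", encoding="utf-8") as handle:
                for entity in sorted(gsm.entries, key=lambda e: e.token):
                    for g in sorted(gsm.entries[entity], key=lambda g: int(g.token)):
                        handle.write(f"{entity.token}\t{g.token}\n")
            paths[name] = str(path)
        ppi_path = out / "ppi.tsv"
        with open(ppi_path, "w", encoding="utf-8") as handle:
            for a, b in sorted(
                (sorted((int(x.token) for x in e)) for e in self.ppi.edges)
            ):
                handle.write(f"{a}\t{b}\n")
        paths["ppi"] = str(ppi_path)
        truth_path = out / "truth.tsv"
        with open(truth_path, "w", encoding="utf-8") as handle:
            for t, d in sorted(self.truth, key=lambda p: (p[0].token, p[1].token)):
                handle.write(f"{t.token}\t{d.token}\n")
        paths["truth"] = str(truth_path)
        return paths


def _sample_sizes(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[int]:
    return [int(x) for x in rng.integers(lo, hi + 1, size=n)]


def generate_fixture(params: FixtureParams | None = None, **overrides) -> Fixture:
    """Generate seeded gene-set tables, a PPI network and the planted truth."""
    if params is None:
        params = FixtureParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)

    need_complex_pool = params.n_complexes * params.complex_set_size[1]
    universe = [str(g) for g in range(1, params.gene_universe_size + 1)]
    perm = rng.permutation(params.gene_universe_size)
    shuffled = [universe[i] for i in perm]
    if need_complex_pool + 2 > params.gene_universe_size:
        raise ValueError(
            "gene_universe_size too small for disjoint complexes plus entity pools"
        )
    complex_pool = shuffled[:need_complex_pool]
    rest = shuffled[need_complex_pool:]
    drug_pool = rest[: len(rest) // 2]
    disease_pool = rest[len(rest) // 2:]
    if not drug_pool or not disease_pool:
        raise ValueError("gene_universe_size leaves no room for drug/disease gene pools")

    # disjoint complexes consumed sequentially from the shuffled pool
    complex_sets: dict[str, set[str]] = {}
    cursor = 0
    width = len(str(params.n_complexes))
    for i, size in enumerate(
        _sample_sizes(rng, params.n_complexes, *params.complex_set_size)
    ):
        token = f"CPX{i + 1:0{width}d}"
        complex_sets[token] = set(complex_pool[cursor:cursor + size])
        cursor += size
    complex_tokens = sorted(complex_sets)

    def sample_pool(pool: list[str], size: int) -> set[str]:
        idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        return {pool[i] for i in sorted(idx)}

    drug_sets = {
        f"DR{i + 1:0{len(str(params.n_drugs))}d}": sample_pool(drug_pool, size)
        for i, size in enumerate(_sample_sizes(rng, params.n_drugs, *params.drug_set_size))
    }
    disease_sets = {
        f"disease{i + 1:0{len(str(params.n_diseases))}d}": sample_pool(disease_pool, size)
        for i, size in enumerate(
            _sample_sizes(rng, params.n_diseases, *params.disease_set_size)
        )
    }
    drug_tokens = sorted(drug_sets)
    disease_tokens = sorted(disease_sets)

    # plant pairs through dedicated (disjoint) complexes
    ppi_pairs: set[tuple[str, str]] = set()
    truth: list[tuple[EntityId, EntityId]] = []
    for i in range(params.n_planted_pairs):
        drug_tok, disease_tok = drug_tokens[i], disease_tokens[i]
        for j in range(i * params.planted_overlap, (i + 1) * params.planted_overlap):
            subunits = sorted(complex_sets[complex_tokens[j]], key=int)
            g1, g2 = (subunits[k] for k in rng.choice(len(subunits), size=2, replace=False))
            drug_sets[drug_tok].add(g1)
            disease_sets[disease_tok].add(g2)
            ppi_pairs.add(tuple(sorted((g1, g2), key=int)))
        truth.append((EntityId("drug", drug_tok), EntityId("disease", disease_tok)))

    # background overlap: a non-planted entity picks up one random subunit
    # of a complex. Planted entities are left untouched so the planted
    # pairs keep their saturated weight and the truth list stays valid by
    # construction.
    if params.background_overlap_prob > 0:
        planted = set(drug_tokens[: params.n_planted_pairs]) | set(
            disease_tokens[: params.n_planted_pairs]
        )
        for sets, tokens in ((drug_sets, drug_tokens), (disease_sets, disease_tokens)):
            for tok in tokens:
                if tok in planted:
                    continue
                for ctok in complex_tokens:
                    if rng.random() < params.background_overlap_prob:
                        subunits = sorted(complex_sets[ctok], key=int)
                        sets[tok].add(subunits[int(rng.integers(len(subunits)))])

    # intra-complex PPI edges
    for ctok in complex_tokens:
        subunits = sorted(complex_sets[ctok], key=int)
        for a in range(len(subunits)):
            for b in range(a + 1, len(subunits)):
                if rng.random() < params.ppi_intra_complex_prob:
                    ppi_pairs.add((subunits[a], subunits[b]))

    return Fixture(
        drugs=GeneSetMap.from_dict("drug", {k: sorted(v, key=int) for k, v in drug_sets.items()}),
        complexes=GeneSetMap.from_dict(
            "complex", {k: sorted(v, key=int) for k, v in complex_sets.items()}
        ),
        diseases=GeneSetMap.from_dict(
            "disease", {k: sorted(v, key=int) for k, v in disease_sets.items()}
        ),
        ppi=PPINetwork.from_pairs(sorted(ppi_pairs)),
        truth=truth,
        params=params,
    )


def generate_planted_blocks(
    n_blocks: int = 4,
    block_size: int = 6,
    intra_weight: tuple[float, float] = (0.7, 1.0),
    inter_prob: float = 0.05,
    inter_weight: tuple[float, float] = (0.01, 0.1),
    seed: int = 0,
) -> tuple[ProjectedGraph, list[frozenset[EntityId]]]:
    """Weighted graph of dense planted blocks with sparse weak inter-block edges.

    Used to exercise the overlapping-clustering stage: blocks are complete
    subgraphs with heavy weights, inter-block edges are rare and light.
    Returns the graph and the planted memberships.
    """
    if n_blocks < 1 or block_size < 2:
        raise ValueError("need n_blocks >= 1 and block_size >= 2")
    rng = np.random.default_rng(seed)
    width = len(str(n_blocks * block_size))
    nodes = [
        EntityId("drug", f"N{i + 1:0{width}d}") for i in range(n_blocks * block_size)
    ]
    blocks = [
        frozenset(nodes[b * block_size:(b + 1) * block_size]) for b in range(n_blocks)
    ]
    edges: dict[tuple[EntityId, EntityId], float] = {}
    for block in blocks:
        members = sorted(block, key=lambda n: n.token)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges[(members[i], members[j])] = float(rng.uniform(*intra_weight))
    for a in range(n_blocks):
        for b in range(a + 1, n_blocks):
            for u in sorted(blocks[a], key=lambda n: n.token):
                for v in sorted(blocks[b], key=lambda n: n.token):
                    if rng.random() < inter_prob:
                        edges[(u, v)] = float(rng.uniform(*inter_weight))
    return ProjectedGraph(role="drug", edges=edges), blocks
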
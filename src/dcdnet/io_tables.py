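"""Readers and writers for the plain-text tables the pipeline consumes.

Canonical formats
-----------------
* gene-set tables: long two-column TSV ``entity<TAB>gene`` (a wide variant
  ``entity<TAB>gene,gene,...`` is supported behind a flag),
* PPI edge lists: two-column TSV of Entrez gene IDs,
* weighted edge lists: three-column TSV ``source<TAB>target<TAB>weight``,
* Cytoscape SIF export (tab-delimited variant) plus an edge-attribute TSV.

All identifiers are handled as :class:`EntityId` values with a fixed role.
Gene tokens must parse as positive integers (Entrez style); disease names
are free text and compared case-insensitively after trimming.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from dcdnet.tripartite import WeightedBipartiteGraph

logger = logging.getLogger(__name__)

ROLES = ("drug", "complex", "disease", "gene")

EvidenceTag = str  # one of {"curated", "inferred", "unknown"}


class ParseError(ValueError):
    """A malformed line in an input table; carries the 1-based line number."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = str(path) if path is not None else None
        self.line = line


@dataclass(frozen=True, slots=True)
class EntityId:
    """An identifier with a fixed role: drug, complex, disease or gene."""

    role: str
    token: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        token = self.token.strip()
        if not token:
            raise ValueError("entity token is empty")
        object.__setattr__(self, "token", token)
        if self.role == "gene":
            try:
                value = int(token)
            except ValueError:
                raise ValueError(f"gene token {token!r} is not an integer") from None
            if value <= 0:
                raise ValueError(f"gene token {token!r} is not a positive integer")

    @classmethod
    def gene(cls, token: str | int) -> "EntityId":
        return cls("gene", str(token))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token


def _folded(name: str) -> str:
    """Matching key for free-text names: trimmed and case-folded."""
    return name.strip().casefold()


@dataclass
class GeneSetMap:
    """Mapping from entities of one role to their non-empty gene sets."""

    role: str
    entries: dict[EntityId, frozenset[EntityId]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        for entity, genes in self.entries.items():
            if entity.role != self.role:
                raise ValueError(f"entity {entity.token!r} has role {entity.role}, expected {self.role}")
            if not genes:
                raise ValueError(f"entity {entity.token!r} has an empty gene set")
            for g in genes:
                if g.role != "gene":
                    raise ValueError(f"member {g.token!r} of {entity.token!r} is not a gene")

    @classmethod
    def from_dict(cls, role: str, mapping: dict[str, Iterable[str | int]]) -> "GeneSetMap":
        """Build from plain tokens, e.g. ``{"DB00001": [5243, 1576]}``."""
        entries = {
            EntityId(role, token): frozenset(EntityId.gene(g) for g in genes)
            for token, genes in mapping.items()
        }
        return cls(role=role, entries=entries)

    def __contains__(self, entity: EntityId) -> bool:
        return entity in self.entries

    def __getitem__(self, entity: EntityId) -> frozenset[EntityId]:
        return self.entries[entity]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[EntityId]:
        return iter(self.entries)

    def genes(self, entity: EntityId) -> frozenset[EntityId]:
        if entity not in self.entries:
            raise LookupError(f"unknown {self.role} {entity.token!r}")
        return self.entries[entity]

    @property
    def n_entities(self) -> int:
        return len(self.entries)

    @property
    def n_genes(self) -> int:
        return len(self.gene_universe())

    @property
    def n_pairs(self) -> int:
        """Distinct (entity, gene) pairs."""
        return sum(len(s) for s in self.entries.values())

    def gene_universe(self) -> frozenset[EntityId]:
        out: set[EntityId] = set()
        for s in self.entries.values():
            out.update(s)
        return frozenset(out)

    def drop_empty(self) -> "GeneSetMap":
        """Return a copy without empty-set entries (warns per drop)."""
        kept = {}
        for entity, genes in self.entries.items():
            if genes:
                kept[entity] = genes
            else:  # pragma: no cover - construction forbids this path normally
                logger.warning("dropping %s %r: empty gene set", self.role, entity.token)
        return GeneSetMap(role=self.role, entries=kept)


@dataclass
class PPINetwork:
    """Undirected, unweighted protein-protein interaction network."""

    nodes: frozenset[EntityId] = frozenset()
    edges: frozenset[frozenset[EntityId]] = frozenset()

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("PPI edges must join two distinct genes (no self-loops)")
            if not e <= self.nodes:
                raise ValueError("PPI edge endpoint missing from node set")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str | int, str | int]]) -> "PPINetwork":
        nodes: set[EntityId] = set()
        edges: set[frozenset[EntityId]] = set()
        for a, b in pairs:
            ga, gb = EntityId.gene(a), EntityId.gene(b)
            nodes.update((ga, gb))
            if ga != gb:
                edges.add(frozenset((ga, gb)))
        return cls(nodes=frozenset(nodes), edges=frozenset(edges))

    @classmethod
    def complete(cls, genes: Iterable[EntityId]) -> "PPINetwork":
        """Complete graph over the given genes (useful as a null filter)."""
        gs = sorted(set(genes), key=lambda g: int(g.token))
        edges = frozenset(
            frozenset((gs[i], gs[j])) for i in range(len(gs)) for j in range(i + 1, len(gs))
        )
        return cls(nodes=frozenset(gs), edges=edges)

    def has_edge(self, a: EntityId, b: EntityId) -> bool:
        return a != b and frozenset((a, b)) in self.edges

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class KnownAssociationTable:
    """Known (drug, disease) pairs with an evidence tag, for benchmarking.

    Disease names are matched case-insensitively after trimming.
    """

    records: dict[tuple[str, str], EvidenceTag] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str] | tuple[str, str, EvidenceTag]]
    ) -> "KnownAssociationTable":
        records: dict[tuple[str, str], EvidenceTag] = {}
        for row in pairs:
            drug, disease = row[0], row[1]
            tag = row[2] if len(row) > 2 else "unknown"
            if tag not in ("curated", "inferred", "unknown"):
                raise ValueError(f"bad evidence tag {tag!r}")
            records[(drug.strip(), _folded(disease))] = tag
        return cls(records=records)

    def __len__(self) -> int:
        return len(self.records)

    def contains(self, drug_token: str, disease_name: str) -> bool:
        return (drug_token.strip(), _folded(disease_name)) in self.records


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-blank tab-split lines."""
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            yield lineno, line.split("\t")


def _is_int(token: str) -> bool:
    try:
        int(token.strip())
    except ValueError:
        return False
    return True


def _is_float(token: str) -> bool:
    try:
        float(token.strip())
    except ValueError:
        return False
    return True


def read_gene_set_table(path: str | Path, role: str, *, wide: bool = False) -> GeneSetMap:
    """Read an entity->gene table into a :class:`GeneSetMap`.

    Long format (default): one ``entity<TAB>gene`` pair per line. Wide
    format: ``entity<TAB>gene,gene,...``. A first line whose gene column is
    not numeric is treated as a header. Duplicate pairs collapse.
    """
    rows: list[tuple[int, str, str]] = []  # (lineno, entity token, gene field)
    n_raw_pairs = 0
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(fields)}", path=path, line=lineno
            )
        entity_token, gene_field = fields[0].strip(), fields[1].strip()
        if first:
            first = False
            probe = gene_field.split(",")[0] if wide else gene_field
            if not _is_int(probe):
                continue  # header line
        rows.append((lineno, entity_token, gene_field))
    if not rows:
        raise ParseError("no data rows", path=path)

    mapping: dict[str, set[str]] = {}
    for lineno, entity_token, gene_field in rows:
        gene_tokens = gene_field.split(",") if wide else [gene_field]
        for g in gene_tokens:
            g = g.strip()
            if not _is_int(g) or int(g) <= 0:
                raise ParseError(f"gene token {g!r} is not a positive integer", path=path, line=lineno)
            mapping.setdefault(entity_token, set()).add(g)
            n_raw_pairs += 1

    gsm = GeneSetMap.from_dict(role, {k: sorted(v, key=int) for k, v in mapping.items()})
    logger.info(
        "read %s table %s: %d entities, %d distinct genes, %d distinct pairs (%d raw)",
        role, path, gsm.n_entities, gsm.n_genes, gsm.n_pairs, n_raw_pairs,
    )
    return gsm


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a two-column gene-gene edge list; undirected, self-loops dropped."""
    pairs: list[tuple[str, str]] = []
    n_loops = 0
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(fields)}", path=path, line=lineno
            )
        a, b = fields[0].strip(), fields[1].strip()
        if first:
            first = False
            if not (_is_int(a) and _is_int(b)):
                continue  # header
        for tok in (a, b):
            if not _is_int(tok):
                raise ParseError(f"gene token {tok!r} is not an integer", path=path, line=lineno)
        if a == b:
            n_loops += 1
            continue
        pairs.append((a, b))
    if n_loops:
        logger.warning("read_ppi %s: dropped %d self-loop(s)", path, n_loops)
    net = PPINetwork.from_pairs(pairs)
    if net.n_edges == 0:
        logger.warning("read_ppi %s: empty network", path)
    logger.info("read PPI %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges)
    return net


def read_known_associations(path: str | Path) -> KnownAssociationTable:
    """Read ``drug<TAB>disease[<TAB>evidence]`` rows (evidence defaults to unknown)."""
    rows: list[tuple[str, str, str]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise ParseError(
                f"expected 2 or 3 tab-separated columns, got {len(fields)}", path=path, line=lineno
            )
        tag = fields[2].strip() if len(fields) == 3 else "unknown"
        if tag not in ("curated", "inferred", "unknown"):
            raise ParseError(f"bad evidence tag {tag!r}", path=path, line=lineno)
        rows.append((fields[0], fields[1], tag))
    # header heuristic: a first row whose tag column reads like a column name
    if rows and rows[0][2] not in ("curated", "inferred", "unknown"):  # pragma: no cover
        rows = rows[1:]
    return KnownAssociationTable.from_pairs(rows)


def iter_weighted_edges(graph: object) -> Iterator[tuple[str, str, float]]:
    """Normalize any weighted graph object to (source, target, weight) tokens."""
    if hasattr(graph, "iter_edges"):
        for u, v, w in graph.iter_edges():  # type: ignore[attr-defined]
            yield u.token, v.token, float(w)
        return
    for u, v, w in graph:  # type: ignore[assignment]
        su = u.token if isinstance(u, EntityId) else str(u)
        sv = v.token if isinstance(v, EntityId) else str(v)
        yield su, sv, float(w)


def read_weighted_edges(
    path: str | Path, left_role: str = "drug", right_role: str = "disease"
) -> "WeightedBipartiteGraph":
    """Read a ``source<TAB>target<TAB>weight`` TSV into a weighted bipartite graph.

    Extra columns beyond the third are ignored, so tables written with
    provenance columns round-trip. A header is detected by a non-numeric
    weight column.
    """
    from dcdnet.tripartite import WeightedBipartiteGraph

    edges: dict[tuple[EntityId, EntityId], float] = {}
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(
                f"expected >= 3 tab-separated columns, got {len(fields)}", path=path, line=lineno
            )
        src, dst, w = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if first:
            first = False
            if not _is_float(w):
                continue  # header
        if not _is_float(w):
            raise ParseError(f"weight {w!r} is not numeric", path=path, line=lineno)
        edges[(EntityId(left_role, src), EntityId(right_role, dst))] = float(w)
    return WeightedBipartiteGraph(left_role=left_role, right_role=right_role, edges=edges)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _format_weight(w: float, precision: int | None) -> str:
    if precision is None:
        return repr(float(w))
    return f"{float(w):.{precision}f}"  # round-half-even via IEEE formatting


def _sorted_edges(graph: object) -> list[tuple[str, str, float]]:
    return sorted(iter_weighted_edges(graph), key=lambda e: (-e[2], e[0], e[1]))


def write_weighted_edges(
    graph: object,
    path: str | Path,
    precision: int | None = None,
    *,
    header: tuple[str, str, str] | None = None,
) -> None:
    """Write a weighted edge TSV, sorted by weight desc then source, target.

    ``precision`` is the number of printed decimal places (None = full
    float precision; report tables use 2).
    """
    if precision is not None and precision < 0:
        raise ValueError("precision must be >= 0")
    with open(path, "w", encoding="utf-8") as handle:
        if header is not None:
            handle.write("\t".join(header) + "\n")
        for src, dst, w in _sorted_edges(graph):
            handle.write(f"{src}\t{dst}\t{_format_weight(w, precision)}\n")


def export_sif(
    graph: object,
    path: str | Path,
    relation_label: str = "assoc",
    *,
    attribute_path: str | Path | None = None,
) -> None:
    """Export to tab-delimited Cytoscape SIF plus a weight edge-attribute file.

    The tab-delimited SIF variant is used so free-text node names that
    contain spaces need no quoting.
    """
    path = Path(path)
    if attribute_path is None:
        attribute_path = path.with_suffix(".edges.tsv")
    edges = _sorted_edges(graph)
    with open(path, "w", encoding="utf-8") as handle:
        for src, dst, _ in edges:
            handle.write(f"{src}\t{relation_label}\t{dst}\n")
    with open(attribute_path, "w", encoding="utf-8") as handle:
        for src, dst, w in edges:
            handle.write(f"{src} ({relation_label}) {dst}\t{_format_weight(w, None)}\n")
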
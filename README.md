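# dcdnet

Weighted drug–complex–disease network inference for drug repositioning.

`dcdnet` builds a weighted tripartite network from three plain-text tables
(drug → target genes, protein complex → subunit genes, disease → related
genes), scores each cross-layer link by symmetric conditional probability
(`|A∩B|² / (|A|·|B|)`), and derives a weighted drug–disease bipartite
network from shared complex neighborhoods (with a direct gene-overlap
fallback for complex-disconnected pairs). Candidate associations are then

1. filtered by **PPI support** — a drug target and a disease gene inside a
   shared complex must interact directly in a binary protein–protein
   interaction network — and an inclusive weight threshold (default 0.50),
2. projected onto one-mode drug–drug / disease–disease networks
   (min-over-shared-neighbors weighting),
3. decomposed into connected-component modules and overlapping clusters
   (cohesiveness-growth clustering, minimum density 0.35),
4. ranked and annotated against a known drug–disease association table.

A seeded synthetic-fixture generator with planted drug–disease
associations makes the whole pipeline testable without any downloads.

## Test

```sh
python -m pytest tests/
```

Note: the full-data reproduction tests in
`tests/test_acceptance.py::TestFullDataReproduction` require the original
published input tables under `data/supplementary/` (drug_targets.tsv,
complex_subunits.tsv, disease_genes.tsv, ppi.tsv). They fail with an
explanatory message when those files are absent; everything else passes
offline.

## CLI

Every stage is a subcommand that reads/writes TSV and drops a JSON run
manifest; outputs are byte-identical on rerun.

```sh
# seeded synthetic inputs with 5 planted drug-disease pairs
dcdnet simulate --seed 7 --out run/fixture

# tripartite layers (drug-complex, complex-disease)
dcdnet build   --drugs run/fixture/drugs.tsv --complexes run/fixture/complexes.tsv \
               --diseases run/fixture/diseases.tsv --out run/build

# weighted drug-disease candidate network (provenance + supporting complexes)
dcdnet derive  --drugs run/fixture/drugs.tsv --complexes run/fixture/complexes.tsv \
               --diseases run/fixture/diseases.tsv --out run/derive

# PPI-support filter + inclusive weight threshold
dcdnet filter  --drugs run/fixture/drugs.tsv --complexes run/fixture/complexes.tsv \
               --diseases run/fixture/diseases.tsv \
               --edges run/derive/drug_disease.tsv --ppi run/fixture/ppi.tsv \
               --min-weight 0.5 --out run/filter

# one-mode projection + connected-component modules
dcdnet project --edges run/filter/drug_disease_filtered.tsv --side drug --out run/project

# overlapping clusters in the projected network
dcdnet cluster --edges run/project/drug_drug.tsv --min-density 0.35 --out run/cluster

# ranked associations, optionally annotated against a known-association table
dcdnet rank    --edges run/filter/drug_disease_filtered.tsv --out run/rank

# hub statistics, weight histogram, full ranked table
dcdnet report  --edges run/derive/drug_disease.tsv --out run/report
```

`simulate` also accepts a YAML config (`--config fixture.yaml`) with any
`FixtureParams` field; flags override the file.

## Package layout

| module | role |
| --- | --- |
| `dcdnet.io_tables` | typed IDs, gene-set/PPI/edge-table readers and writers, SIF export |
| `dcdnet.tripartite` | overlap weighting, bipartite layers, tripartite assembly |
| `dcdnet.derivation` | drug–disease derivation incl. fallback rule and provenance |
| `dcdnet.filtering` | PPI-support filter, inclusive weight threshold |
| `dcdnet.projection` | one-mode projections, components, hub statistics |
| `dcdnet.clustering` | cohesiveness-growth overlapping clustering |
| `dcdnet.report` | ranking, benchmark annotation, weight histograms |
| `dcdnet.simulate` | seeded synthetic fixtures with planted associations |
| `dcdnet.cli` | stage-by-stage command line with run manifests |
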
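# echonom

A deterministic gene-nomenclature pipeline for echinoderm genomes. Given
per-tool ortholog prediction tables, a reference (human) gene table, gene
models (GFF3 + FASTA) and optional all-vs-all similarity hits, it assigns
standardized lowercase gene symbols and full names to every gene, with full
rule provenance:

* **Consensus orthology** — a gene pair is an ortholog when ≥3 distinct
  prediction tools support it (inclusive threshold); supported edges are
  partitioned into orthology groups labeled one:one / one:many / many:one /
  many:many / orphan.
* **Pseudoduplicate detection** — gene-model sequences (introns plus 1 kb
  of flank) matching at ≥90% identity over ≥90% of the longer sequence's
  length are chained into clusters of putative under-collapsed haplotypes.
* **Naming cascade** — one:one groups adopt the human identifier; one:many
  ties are resolved by tool support, then a shared family stem, then
  curator overrides, then alphanumeric order; pseudoduplicates get `.a/.b`
  letter suffixes; paralog expansions get `.1/.2` suffixes kept equal
  across species where one:one cross-species links exist; everything else
  falls back to `loc<entrez-id>`.
* **Symbol normalization** — Greek letters → Latin letters, trailing Roman
  numerals → Arabic digits, lowercase, machine-readable character set;
  legacy identifiers are relegated to synonym lists.
* **Reporting** — nameability category counts and shares with half-up
  rounding at per-value precision.

A fixtures module generates fully synthetic cohorts with planted ground
truth for every branch, so the entire pipeline is testable offline.

## CLI

```sh
# write a synthetic demo cohort (plus truth.json with the planted answers)
echonom fixtures --seed 1 --out demo/cohort --second-species

# full chain: consensus -> pseudodup -> assign -> report (+ manifest.json)
echonom run --cohort demo/cohort --out demo/results

# individual stages
echonom consensus --tables-dir demo/cohort --out-edges edges.tsv --out-groups groups.tsv
echonom pseudodup --hits demo/cohort/similarity.tsv --gff3 demo/cohort/genes.gff3 \
    --fasta demo/cohort/genome.fa --out-clusters clusters.tsv --out-bed clusters.bed
echonom report --n-total 27447 --n-human 5710 --n-vertebrate 1392 --n-invertebrate 964
```

Thresholds (`--min-tools`, `--identity`, `--coverage`, `--flank`) may also
be set in a YAML config passed with `--config`; command-line flags win.

### Input formats

* `ortholog_<tool>.tsv` — one normalized table per tool, columns
  `query`, `subject`, `taxon` (taxon ∈ human / other_vertebrate /
  invertebrate / non_animal). The upstream tools' native outputs must be
  normalized to this layout by the user.
* `reference.tsv` — `symbol`, `name`, `stem`, `taxon` (stem may be blank).
* `genes.gff3` + `genome.fa` — gene/exon features; `Dbxref=GeneID:...`
  supplies the Entrez ID used by the `loc` fallback, `product` the
  predicted-product name, `Alias` legacy identifiers.
* `similarity.tsv` — BLAST outfmt-6-style tabular all-vs-all hits of the
  extracted gene-model sequences (self-hits dropped on read).
* `legacy.tsv`, `overrides.tsv`, `cross_links.tsv` — optional legacy
  identifiers, curator tie-break overrides, and supported one:one
  cross-species gene pairs used for stem blocking and suffix inheritance.

## Library use

```python
from echonom import (NomenclatureConfig, tally_support,
                     cluster_pseudoduplicates, assign_identifiers)
from echonom.fixtures import CohortSpec, generate_cohort

cohort = generate_cohort(seed=1, spec=CohortSpec())
edges = tally_support(cohort.all_calls, cohort.config)
clusters = cluster_pseudoduplicates(cohort.similarity_hits, cohort.config)
assignments = assign_identifiers(
    cohort.genes, edges, clusters, cohort.reference,
    cohort.overrides, cohort.cross_links, cohort.config,
)
```
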
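"""Readers and writers for every external format the pipeline touches.

All parsing lives here so that the analysis modules only ever see typed
objects.  Conventions:

* coordinates are GFF3-style 1-based inclusive everywhere; conversion to
  0-based slices happens only inside sequence extraction;
* tab-separated tables carry a header row and are written in a
  deterministic order so reruns are byte-identical;
* the taxon vocabulary is the closed set ``{human, other_vertebrate,
  invertebrate, non_animal}`` and readers normalize case.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

TAXA = frozenset({"human", "other_vertebrate", "invertebrate", "non_animal"})

#: canonical BLAST outfmt-6 column order; extra trailing columns are ignored
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class FormatError(ValueError):
    """Raised when an input file violates its documented layout."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One annotated gene model.

    ``start``/``end`` and exon coordinates are 1-based inclusive.  Exons must
    be sorted, non-overlapping, and contained in the gene span.
    """

    species: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    entrez_id: int | None = None
    product: str | None = None
    legacy_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon {s}..{e} inverted")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon {s}..{e} outside gene span "
                    f"{self.start}..{self.end}"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons overlap or are unsorted at {s}"
                )
            prev_end = e
        if self.entrez_id is not None and self.entrez_id <= 0:
            raise ValueError(f"{self.gene_id}: entrez_id must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class OrthologCall:
    """A single tool's prediction that ``query_id`` is orthologous to
    ``subject_id`` (a reference-set gene in ``subject_taxon``)."""

    tool: str
    query_id: str
    subject_id: str
    subject_taxon: str

    def __post_init__(self) -> None:
        if self.subject_taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.subject_taxon!r}")


@dataclass(frozen=True)
class ReferenceGene:
    symbol: str
    full_name: str
    family_stem: str | None
    taxon: str

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")


@dataclass(frozen=True)
class SimilarityHit:
    """One row of an all-vs-all similarity search between gene-model
    sequences, with the full sequence lengths attached."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    q_len: int
    s_len: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} out of [0,100]")
        if self.query_id == self.subject_id:
            raise ValueError("self-hit survived filtering")
        if min(self.aln_length, self.q_len, self.s_len) <= 0:
            raise ValueError("lengths must be positive")


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def _open_tsv(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(lineno, fields), ...]) for a tab-separated file."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [(i + 1, row) for i, row in enumerate(reader) if row]
    if not rows:
        return [], []
    header = [h.strip().lower() for h in rows[0][1]]
    return header, rows[1:]


def _require_columns(header: Sequence[str], needed: Iterable[str], path) -> dict:
    idx = {}
    for col in needed:
        if col not in header:
            raise FormatError(f"{path}: missing required column {col!r}")
        idx[col] = header.index(col)
    return idx


def read_ortholog_table(path, tool: str) -> list[OrthologCall]:
    """Read one tool's normalized ortholog table (columns query, subject,
    taxon).  Duplicate (query, subject) rows are collapsed."""
    header, rows = _open_tsv(path)
    if not header:
        log.warning("%s: empty ortholog table for tool %s", path, tool)
        return []
    idx = _require_columns(header, ("query", "subject", "taxon"), path)
    calls: list[OrthologCall] = []
    seen: set[tuple[str, str]] = set()
    bad: list[int] = []
    for lineno, row in rows:
        if len(row) < len(header):
            bad.append(lineno)
            continue
        query = row[idx["query"]].strip()
        subject = row[idx["subject"]].strip()
        taxon = row[idx["taxon"]].strip().lower()
        if not query or not subject or taxon not in TAXA:
            bad.append(lineno)
            continue
        if (query, subject) in seen:
            continue
        seen.add((query, subject))
        calls.append(OrthologCall(tool, query, subject, taxon))
    if bad:
        raise FormatError(
            f"{path}: malformed rows at lines {', '.join(map(str, bad))}"
        )
    return calls


def read_reference_genes(path) -> dict[str, ReferenceGene]:
    """Read the reference gene table (symbol / name / stem / taxon), keyed
    by symbol.  Blank stems are stored as None."""
    header, rows = _open_tsv(path)
    idx = _require_columns(header, ("symbol", "name", "stem", "taxon"), path)
    out: dict[str, ReferenceGene] = {}
    first_line: dict[str, int] = {}
    for lineno, row in rows:
        symbol = row[idx["symbol"]].strip()
        if symbol in out:
            raise FormatError(
                f"{path}: duplicate symbol {symbol!r} at lines "
                f"{first_line[symbol]} and {lineno}"
            )
        stem = row[idx["stem"]].strip() or None
        out[symbol] = ReferenceGene(
            symbol=symbol,
            full_name=row[idx["name"]].strip(),
            family_stem=stem,
            taxon=row[idx["taxon"]].strip().lower(),
        )
        first_line[symbol] = lineno
    return out


def read_similarity_hits(
    path, gene_lengths: Mapping[str, int]
) -> list[SimilarityHit]:
    """Read BLAST outfmt-6-style tabular hits.  Self-hits are dropped;
    q_len/s_len are resolved from *gene_lengths* (full gene-model sequence
    lengths).  A hit naming an unknown gene is a hard error."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns"
                )
            q, s = fields[0], fields[1]
            if q == s:
                continue
            for gid in (q, s):
                if gid not in gene_lengths:
                    raise FormatError(
                        f"{path}:{lineno}: unknown gene {gid!r} "
                        "(no length available)"
                    )
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    q_len=gene_lengths[q],
                    s_len=gene_lengths[s],
                )
            )
    return hits


def read_legacy_table(path) -> dict[str, list[str]]:
    """Read the legacy-identifier table (gene_id, legacy_id); order of rows
    per gene is the historical order, oldest first."""
    header, rows = _open_tsv(path)
    idx = _require_columns(header, ("gene_id", "legacy_id"), path)
    out: dict[str, list[str]] = {}
    for _, row in rows:
        out.setdefault(row[idx["gene_id"]].strip(), []).append(
            row[idx["legacy_id"]].strip()
        )
    return out


def read_override_table(path) -> dict[str, tuple[str, str, str]]:
    """Read curator overrides: gene_id -> (forced_symbol, forced_name, note)."""
    header, rows = _open_tsv(path)
    idx = _require_columns(header, ("gene_id", "symbol", "name"), path)
    note_i = header.index("note") if "note" in header else None
    out: dict[str, tuple[str, str, str]] = {}
    for lineno, row in rows:
        gid = row[idx["gene_id"]].strip()
        if gid in out:
            raise FormatError(f"{path}:{lineno}: duplicate override for {gid}")
        note = row[note_i].strip() if note_i is not None and len(row) > note_i else ""
        out[gid] = (row[idx["symbol"]].strip(), row[idx["name"]].strip(), note)
    return out


def read_cross_links(path) -> list[tuple[str, str]]:
    """Read supported one:one cross-species gene pairs (gene_a, gene_b)."""
    header, rows = _open_tsv(path)
    idx = _require_columns(header, ("gene_a", "gene_b"), path)
    return [
        (row[idx["gene_a"]].strip(), row[idx["gene_b"]].strip())
        for _, row in rows
    ]


# ---------------------------------------------------------------------------
# gene models (GFF3 + FASTA)
# ---------------------------------------------------------------------------


def read_gene_models(
    gff3_path, fasta_path, species: str = "echi"
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Load gene models from GFF3 plus their genome FASTA.

    Exons are attached to genes through Parent relations (possibly via an
    mRNA level).  Entrez IDs are taken from ``Dbxref=GeneID:...``, product
    names from a ``product`` or ``description`` attribute, legacy
    identifiers from ``Alias``, and a per-gene ``species`` attribute (when
    present) overrides the *species* argument.
    """
    import gffutils
    from Bio import SeqIO

    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise FormatError(
                f"gene {gene.id} references missing sequence {gene.seqid!r}"
            )
        if gene.end > len(genome[gene.seqid]):
            raise FormatError(
                f"gene {gene.id} extends past end of {gene.seqid}"
            )
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        for s, e in exons:
            if s < gene.start or e > gene.end:
                raise FormatError(
                    f"exon {s}..{e} outside gene {gene.id} span"
                )
        entrez = None
        for xref in gene.attributes.get("Dbxref", []):
            if xref.startswith("GeneID:"):
                entrez = int(xref.split(":", 1)[1])
        product = (
            gene.attributes.get("product", [None])[0]
            or gene.attributes.get("description", [None])[0]
        )
        records.append(
            GeneRecord(
                species=gene.attributes.get("species", [species])[0],
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
                entrez_id=entrez,
                product=product,
                legacy_ids=list(gene.attributes.get("Alias", [])),
            )
        )
    records.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise FormatError(f"duplicate gene id {rec.gene_id}")
        seen.add(rec.gene_id)
    return records, genome


# ---------------------------------------------------------------------------
# writers (deterministic, round-trippable)
# ---------------------------------------------------------------------------


def _write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_ortholog_table(path, calls: Iterable[OrthologCall]) -> None:
    rows = sorted(
        {(c.query_id, c.subject_id, c.subject_taxon) for c in calls}
    )
    _write_tsv(path, ("query", "subject", "taxon"), rows)


def write_reference_table(path, genes: Mapping[str, ReferenceGene]) -> None:
    rows = [
        (g.symbol, g.full_name, g.family_stem or "", g.taxon)
        for g in sorted(genes.values(), key=lambda g: g.symbol)
    ]
    _write_tsv(path, ("symbol", "name", "stem", "taxon"), rows)


def write_similarity_hits(path, hits: Iterable[SimilarityHit]) -> None:
    """Write hits as canonical 12-column BLAST outfmt 6 (unused score
    columns are filled with neutral values)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            mismatch = max(
                0, round(h.aln_length * (100.0 - h.pct_identity) / 100.0)
            )
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.aln_length}\t{mismatch}\t0\t1\t{h.aln_length}\t1\t"
                f"{h.aln_length}\t0.0\t{h.aln_length}\n"
            )


def write_legacy_table(path, legacy: Mapping[str, Sequence[str]]) -> None:
    rows = [
        (gid, lid)
        for gid in sorted(legacy)
        for lid in legacy[gid]
    ]
    _write_tsv(path, ("gene_id", "legacy_id"), rows)


def write_override_table(path, overrides: Mapping[str, tuple]) -> None:
    rows = [
        (gid, *overrides[gid])
        for gid in sorted(overrides)
    ]
    _write_tsv(path, ("gene_id", "symbol", "name", "note"), rows)


def write_cross_links(path, links: Iterable[tuple[str, str]]) -> None:
    _write_tsv(path, ("gene_a", "gene_b"), sorted(set(links)))


def write_fasta(path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path, genes: Iterable[GeneRecord]) -> None:
    """Write gene + mRNA + exon features; attributes carry entrez id,
    product and legacy aliases so read_gene_models round-trips."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = [f"ID={g.gene_id}", f"species={g.species}"]
            if g.entrez_id is not None:
                attrs.append(f"Dbxref=GeneID:{g.entrez_id}")
            if g.product:
                attrs.append(f"product={g.product}")
            if g.legacy_ids:
                attrs.append("Alias=" + ",".join(g.legacy_ids))
            fh.write(
                f"{g.chrom}\techonom\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{';'.join(attrs)}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\techonom\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# assignment output
# ---------------------------------------------------------------------------

ASSIGNMENT_COLUMNS = (
    "species",
    "gene_id",
    "symbol",
    "full_name",
    "rule_fired",
    "chosen_ortholog",
    "support_count",
    "pseudodup_cluster",
    "suffix",
    "synonyms",
)


def write_assignments(path, assignments) -> None:
    """Write the final assignment table, sorted by (species, gene_id).

    Raises if two assignments in one species share a symbol — uniqueness is
    enforced upstream; this is the last line of defense.
    """
    seen: dict[tuple[str, str], str] = {}
    for a in assignments:
        key = (a.species, a.symbol)
        if key in seen:
            raise ValueError(
                f"symbol {a.symbol!r} assigned to both {seen[key]} and "
                f"{a.gene_id} in species {a.species}"
            )
        seen[key] = a.gene_id
    rows = [
        (
            a.species,
            a.gene_id,
            a.symbol,
            a.full_name,
            a.rule_fired,
            a.chosen_ortholog or "",
            "" if a.support_count is None else a.support_count,
            a.pseudodup_cluster or "",
            a.suffix or "",
            ";".join(a.synonyms),
        )
        for a in sorted(assignments, key=lambda a: (a.species, a.gene_id))
    ]
    _write_tsv(path, ASSIGNMENT_COLUMNS, rows)


def read_assignments(path):
    """Re-parse an assignment table written by :func:`write_assignments`."""
    from .naming import Assignment

    header, rows = _open_tsv(path)
    idx = _require_columns(header, ASSIGNMENT_COLUMNS, path)
    out = []
    for _, row in rows:
        get = lambda col: row[idx[col]]
        out.append(
            Assignment(
                gene_id=get("gene_id"),
                species=get("species"),
                symbol=get("symbol"),
                full_name=get("full_name"),
                rule_fired=get("rule_fired"),
                chosen_ortholog=get("chosen_ortholog") or None,
                support_count=(
                    int(get("support_count")) if get("support_count") else None
                ),
                pseudodup_cluster=get("pseudodup_cluster") or None,
                suffix=get("suffix") or None,
                synonyms=get("synonyms").split(";") if get("synonyms") else [],
            )
        )
    return out


def write_synonym_table(path, assignments) -> None:
    """Map every legacy identifier to its current symbol."""
    rows = sorted(
        (syn, a.symbol, a.gene_id, a.species)
        for a in assignments
        for syn in a.synonyms
    )
    _write_tsv(path, ("synonym", "symbol", "gene_id", "species"), rows)
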
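"""Pseudoduplicate detection.

Highly polymorphic genomes assemble with under-collapsed heterozygosity:
both haplotypes of a locus survive as separate gene models.  Such "genes"
confound orthology, so gene-model sequences (introns plus flanking bases
included) are compared all-vs-all and pairs matching at >=90% identity over
>=90% of the longer sequence's length are chained into clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .consensus import NomenclatureConfig
from .io_formats import GeneRecord, SimilarityHit

log = logging.getLogger(__name__)


@dataclass
class PseudodupCluster:
    """A connected set (size >= 2) of mutually similar gene models."""

    members: list[str]
    evidence: list[SimilarityHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a pseudoduplicate cluster needs >= 2 members")
        self.members = sorted(self.members)


def extract_gene_model_sequence(
    gene: GeneRecord, genome: Mapping[str, str], flank_bp: int
) -> str:
    """Slice the gene model plus up to *flank_bp* bases either side.

    The slice is reported on the forward genome strand regardless of the
    gene's strand, and is clipped (with a warning) at contig bounds.
    """
    if gene.chrom not in genome:
        raise KeyError(f"{gene.gene_id}: unknown contig {gene.chrom!r}")
    contig = genome[gene.chrom]
    if gene.start < 1 or gene.end > len(contig):
        raise ValueError(
            f"{gene.gene_id}: span {gene.start}..{gene.end} outside "
            f"contig {gene.chrom} (len {len(contig)})"
        )
    lo = gene.start - flank_bp
    hi = gene.end + flank_bp
    if lo < 1:
        log.warning(
            "%s: upstream flank clipped to %d bases",
            gene.gene_id, gene.start - 1,
        )
        lo = 1
    if hi > len(contig):
        log.warning(
            "%s: downstream flank clipped to %d bases",
            gene.gene_id, len(contig) - gene.end,
        )
        hi = len(contig)
    return contig[lo - 1 : hi]


def hit_passes(hit: SimilarityHit, config: NomenclatureConfig) -> bool:
    """The 90/90 rule: identity and coverage-of-the-longer-sequence must
    both meet their thresholds; both comparisons are inclusive."""
    longer = max(hit.q_len, hit.s_len)
    if hit.aln_length > longer:
        raise ValueError(
            f"hit {hit.query_id}/{hit.subject_id}: alignment length "
            f"{hit.aln_length} exceeds longer sequence length {longer}"
        )
    coverage = hit.aln_length / longer * 100.0
    return (
        hit.pct_identity >= config.identity_threshold
        and coverage >= config.coverage_threshold
    )


def best_hits(hits: Iterable[SimilarityHit]) -> dict[tuple[str, str], SimilarityHit]:
    """Keep the single best HSP per ordered pair (max aln_length, ties
    broken by pct_identity)."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.aln_length, h.pct_identity) > (
            cur.aln_length, cur.pct_identity
        ):
            best[key] = h
    return best


def cluster_pseudoduplicates(
    hits: Sequence[SimilarityHit], config: NomenclatureConfig
) -> list[PseudodupCluster]:
    """Chain passing pairs into connected components.

    A pair passes if the best HSP of *either* orientation passes; singleton
    components are dropped.  Components (not cliques) are used because
    chained pairs reflect one under-collapsed locus.
    """
    best = best_hits(hits)
    graph = nx.Graph()
    passing: dict[frozenset, list[SimilarityHit]] = {}
    for (q, s), h in best.items():
        if hit_passes(h, config):
            graph.add_edge(q, s)
            passing.setdefault(frozenset((q, s)), []).append(h)
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        evidence = [
            h
            for pair, hs in passing.items()
            if pair <= comp
            for h in hs
        ]
        evidence.sort(key=lambda h: (h.query_id, h.subject_id))
        clusters.append(PseudodupCluster(members=members, evidence=evidence))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def compute_similarity_hits(
    sequences: Mapping[str, str],
    min_pct_identity: float = 50.0,
) -> list[SimilarityHit]:
    """All-vs-all pairwise comparison of gene-model sequences.

    A lightweight stand-in for an external BLAST run, adequate at fixture
    scale (quadratic in sequence length).  Identity is computed over the
    alignment (the BLAST ``pident`` convention); hits below
    *min_pct_identity* are suppressed, as a word-based seeder would do.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1

    names = sorted(sequences)
    hits: list[SimilarityHit] = []
    for i, q in enumerate(names):
        for s in names[i + 1 :]:
            aln = aligner.align(sequences[q], sequences[s])[0]
            matches = 0
            columns = 0
            for (qs, qe), (ss, se) in zip(*aln.aligned):
                columns += qe - qs
                matches += sum(
                    a == b
                    for a, b in zip(
                        sequences[q][qs:qe], sequences[s][ss:se]
                    )
                )
            # count gap columns inside the local alignment window
            gaps = (aln.aligned[0][-1][1] - aln.aligned[0][0][0]) - columns
            gaps += (aln.aligned[1][-1][1] - aln.aligned[1][0][0]) - columns
            aln_length = columns + gaps
            if aln_length == 0:
                continue
            pident = matches / aln_length * 100.0
            if pident < min_pct_identity:
                continue
            for a, b in ((q, s), (s, q)):
                hits.append(
                    SimilarityHit(
                        query_id=a,
                        subject_id=b,
                        pct_identity=round(pident, 2),
                        aln_length=aln_length,
                        q_len=len(sequences[a]),
                        s_len=len(sequences[b]),
                    )
                )
    return hits


def write_cluster_table(path, clusters: Sequence[PseudodupCluster]) -> None:
    from .io_formats import _write_tsv

    rows = [
        (f"PD{i:04d}", gid)
        for i, c in enumerate(clusters, 1)
        for gid in c.members
    ]
    _write_tsv(path, ("cluster_id", "gene_id"), rows)


def read_cluster_table(path) -> list[PseudodupCluster]:
    from .io_formats import _open_tsv, _require_columns

    header, rows = _open_tsv(path)
    idx = _require_columns(header, ("cluster_id", "gene_id"), path)
    grouped: dict[str, list[str]] = {}
    for _, row in rows:
        grouped.setdefault(row[idx["cluster_id"]], []).append(
            row[idx["gene_id"]]
        )
    return [
        PseudodupCluster(members=members)
        for _, members in sorted(grouped.items())
    ]


def write_cluster_bed(
    path, clusters: Sequence[PseudodupCluster], genes: Mapping[str, GeneRecord]
) -> None:
    """BED6 of cluster member gene spans (BED is 0-based half-open)."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, 1):
            for gid in c.members:
                g = genes.get(gid)
                if g is None:
                    continue
                fh.write(
                    f"{g.chrom}\t{g.start - 1}\t{g.end}\t"
                    f"PD{i:04d}:{gid}\t0\t{g.strand}\n"
                )
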
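"""Deterministic synthetic cohorts with known ground truth.

Every branch of the naming cascade can be planted on demand: one:one
groups, each one:many tie-breaking outcome, paralog expansions (optionally
mirrored into a second species to exercise cross-species suffix sharing),
pseudoduplicate clusters, vertebrate-only and invertebrate-only genes,
orphans, and sub-threshold noise pairs.  All randomness flows through one
``random.Random(seed)`` (integer decisions only), so regeneration with the
same seed is byte-identical.
"""

from __future__ import annotations

import json
import os
import string
from dataclasses import asdict, dataclass, field
from typing import Iterable

from random import Random

from .consensus import NomenclatureConfig
from .io_formats import (
    GeneRecord,
    OrthologCall,
    ReferenceGene,
    SimilarityHit,
    write_cross_links,
    write_fasta,
    write_gff3,
    write_legacy_table,
    write_ortholog_table,
    write_override_table,
    write_reference_table,
    write_similarity_hits,
)
from .naming import CuratorOverride, letter_suffix, normalize_symbol
from .pseudodup import PseudodupCluster

#: labels only — the artifact never runs these tools
DEFAULT_TOOLS = (
    "inparanoid",
    "proteinortho",
    "swiftortho",
    "fastortho",
    "oma",
    "orthofinder",
)


@dataclass
class CohortSpec:
    """Branch counts and generator knobs for :func:`generate_cohort`."""

    n_one_one: int = 5
    n_one_many_support: int = 2
    n_one_many_stem: int = 2
    n_one_many_curator: int = 1
    n_one_many_alpha: int = 2
    n_many_one: int = 1
    n_many_many: int = 1
    paralogs_per_group: int = 3
    n_pseudodup_clusters: int = 1
    cluster_size: int = 2
    n_vertebrate_one_one: int = 2
    n_invertebrate_only: int = 2
    n_orphan: int = 2
    n_noise: int = 2
    tool_panel: tuple = DEFAULT_TOOLS
    species: str = "spua"
    second_species: str | None = None
    min_tools: int = 3


@dataclass
class PlantedGene:
    gene_id: str
    species: str
    symbol: str
    rule: str
    category: str
    cluster: str | None = None
    suffix: str | None = None


@dataclass
class PlantedTruth:
    seed: int
    per_gene: dict[str, PlantedGene] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "per_gene": {
                gid: asdict(pg) for gid, pg in sorted(self.per_gene.items())
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        payload = json.loads(text)
        return cls(
            seed=payload["seed"],
            params=payload.get("params", {}),
            per_gene={
                gid: PlantedGene(**pg)
                for gid, pg in payload["per_gene"].items()
            },
        )


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` produced, in memory."""

    genes: list[GeneRecord]
    calls_by_tool: dict[str, list[OrthologCall]]
    reference: dict[str, ReferenceGene]
    overrides: dict[str, CuratorOverride]
    cross_links: list[tuple[str, str]]
    similarity_hits: list[SimilarityHit]
    legacy: dict[str, list[str]]
    genome: dict[str, str]
    truth: PlantedTruth
    config: NomenclatureConfig

    @property
    def all_calls(self) -> list[OrthologCall]:
        return [
            c
            for tool in sorted(self.calls_by_tool)
            for c in self.calls_by_tool[tool]
        ]

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        join = lambda name: os.path.join(outdir, name)
        for tool in sorted(self.calls_by_tool):
            write_ortholog_table(
                join(f"ortholog_{tool}.tsv"), self.calls_by_tool[tool]
            )
        write_reference_table(join("reference.tsv"), self.reference)
        write_gff3(join("genes.gff3"), self.genes)
        write_fasta(join("genome.fa"), self.genome)
        write_similarity_hits(join("similarity.tsv"), self.similarity_hits)
        write_legacy_table(join("legacy.tsv"), self.legacy)
        write_override_table(
            join("overrides.tsv"),
            {
                gid: (ov.forced_symbol, ov.forced_name, ov.note)
                for gid, ov in self.overrides.items()
            },
        )
        write_cross_links(join("cross_links.tsv"), self.cross_links)
        with open(join("truth.json"), "w") as fh:
            fh.write(self.truth.to_json() + "\n")


class _Maker:
    """Bookkeeping helpers shared by the branch builders."""

    def __init__(self, rng: Random, spec: CohortSpec):
        self.rng = rng
        self.spec = spec
        self.words: set[str] = set()
        self.gene_n = 0
        self.entrez_n = 500000
        self.genes: list[GeneRecord] = []
        self.calls: list[OrthologCall] = []
        self.reference: dict[str, ReferenceGene] = {}
        self.legacy: dict[str, list[str]] = {}
        self.genome: dict[str, str] = {}

    def word(self, length: int = 4) -> str:
        """A fresh lowercase word, unique across the cohort (so symbol
        stems never collide by accident)."""
        while True:
            w = "".join(
                self.rng.choice(string.ascii_lowercase)
                for _ in range(length)
            )
            if w not in self.words:
                self.words.add(w)
                return w

    def ref(self, symbol: str, taxon: str = "human",
            stem: str | None = None) -> str:
        self.reference[symbol] = ReferenceGene(
            symbol=symbol,
            full_name=f"{symbol.lower()} protein",
            family_stem=stem,
            taxon=taxon,
        )
        return symbol

    def gene(self, species: str, with_legacy: bool = False) -> GeneRecord:
        self.gene_n += 1
        self.entrez_n += self.rng.randint(1, 9)
        gid = f"{species}g{self.gene_n:04d}"
        glen = self.rng.randint(300, 900)
        start = 1201
        end = start + glen - 1
        chrom = f"{species}ctg{self.gene_n:04d}"
        contig_len = end + 1200
        self.genome[chrom] = "".join(
            self.rng.choice("ACGT") for _ in range(contig_len)
        )
        if glen >= 400:
            exons = [(start, start + 120), (start + 200, end)]
        else:
            exons = [(start, end)]
        legacy = []
        if with_legacy:
            legacy = [f"Sp-{self.word(5).capitalize()}"]
        rec = GeneRecord(
            species=species,
            gene_id=gid,
            chrom=chrom,
            start=start,
            end=end,
            strand=self.rng.choice("+-"),
            exons=exons,
            entrez_id=self.entrez_n,
            product=f"hypothetical protein {self.entrez_n}",
            legacy_ids=legacy,
        )
        self.genes.append(rec)
        if legacy:
            self.legacy[gid] = legacy
        return rec

    def edge(self, gene_id: str, symbol: str, taxon: str,
             n_tools: int) -> None:
        for tool in sorted(self.rng.sample(self.spec.tool_panel, n_tools)):
            self.calls.append(OrthologCall(tool, gene_id, symbol, taxon))

    def support(self, lo: int | None = None, hi: int | None = None) -> int:
        lo = self.spec.min_tools if lo is None else lo
        hi = len(self.spec.tool_panel) if hi is None else hi
        return self.rng.randint(lo, hi)


def generate_cohort(
    seed: int,
    spec: CohortSpec | None = None,
    config: NomenclatureConfig | None = None,
) -> Cohort:
    """Build a cohort covering every requested branch, with planted truth."""
    spec = spec or CohortSpec()
    config = config or NomenclatureConfig(min_tools=spec.min_tools)
    if spec.min_tools > len(spec.tool_panel):
        raise ValueError(
            f"infeasible spec: min_tools {spec.min_tools} exceeds panel "
            f"size {len(spec.tool_panel)}"
        )
    rng = Random(seed)
    mk = _Maker(rng, spec)
    truth = PlantedTruth(
        seed=seed,
        params={"min_tools": spec.min_tools,
                "tool_panel": list(spec.tool_panel)},
    )
    sp = spec.species
    overrides: dict[str, CuratorOverride] = {}
    cross_links: list[tuple[str, str]] = []
    similarity_hits: list[SimilarityHit] = []
    noise_candidates: list[str] = []
    clusters_planted: list[list[str]] = []

    def plant(gene: GeneRecord, symbol: str, rule: str, category: str,
              suffix: str | None = None) -> None:
        truth.per_gene[gene.gene_id] = PlantedGene(
            gene_id=gene.gene_id,
            species=gene.species,
            symbol=symbol,
            rule=rule,
            category=category,
            suffix=suffix,
        )

    # --- one:one ----------------------------------------------------------
    for i in range(spec.n_one_one):
        sym = mk.ref(mk.word().upper() + str(rng.randint(1, 9)))
        g = mk.gene(sp, with_legacy=(i % 2 == 0))
        mk.edge(g.gene_id, sym, "human", mk.support())
        plant(g, normalize_symbol(sym), "one_one", "human_one_one")
        noise_candidates.append(g.gene_id)

    # --- one:many, resolved by support ------------------------------------
    for _ in range(spec.n_one_many_support):
        w1, w2 = mk.word(), mk.word()
        s_win = mk.ref(w1.upper() + "1")
        s_lose = mk.ref(w2.upper() + "2")
        g = mk.gene(sp)
        win_n = mk.support(spec.min_tools + 1)
        mk.edge(g.gene_id, s_win, "human", win_n)
        mk.edge(g.gene_id, s_lose, "human",
                mk.support(spec.min_tools, win_n - 1))
        plant(g, normalize_symbol(s_win), "one_many_support",
              "human_one_one")

    # --- one:many, resolved by shared stem --------------------------------
    for _ in range(spec.n_one_many_stem):
        stem = mk.word()
        nums = rng.sample(range(2, 9), 3)
        g = mk.gene(sp)
        tie = mk.support()
        for n in nums:
            sym = mk.ref(stem.upper() + str(n), stem=stem)
            mk.edge(g.gene_id, sym, "human", tie)
        plant(g, stem, "one_many_stem", "human_one_one")

    # --- one:many, resolved by curator ------------------------------------
    for _ in range(spec.n_one_many_curator):
        g = mk.gene(sp)
        tie = mk.support()
        for w in (mk.word(), mk.word()):
            mk.edge(g.gene_id, mk.ref(w.upper() + str(rng.randint(1, 9))),
                    "human", tie)
        forced = "cur" + mk.word()
        overrides[g.gene_id] = CuratorOverride(
            gene_id=g.gene_id,
            forced_symbol=forced,
            forced_name=f"{forced} (curated)",
            note="planted tie resolution",
        )
        plant(g, forced, "one_many_curator", "human_one_one")

    # --- one:many, resolved alphanumerically ------------------------------
    for _ in range(spec.n_one_many_alpha):
        g = mk.gene(sp)
        tie = mk.support()
        syms = [
            mk.ref(mk.word().upper() + str(rng.randint(1, 9)))
            for _ in range(2)
        ]
        for s in syms:
            mk.edge(g.gene_id, s, "human", tie)
        winner = min(syms, key=normalize_symbol)
        plant(g, normalize_symbol(winner), "one_many_alpha",
              "human_one_one")

    # --- many:one (paralog expansion) --------------------------------------
    mirrored_groups: list[tuple[str, list[str]]] = []
    for _ in range(spec.n_many_one):
        sym = mk.ref(mk.word().upper() + str(rng.randint(1, 9)))
        base = normalize_symbol(sym)
        members = []
        for j in range(1, spec.paralogs_per_group + 1):
            g = mk.gene(sp)
            mk.edge(g.gene_id, sym, "human", mk.support())
            plant(g, f"{base}.{j}", "paralog_suffix", "human_one_one",
                  suffix=str(j))
            members.append(g.gene_id)
        mirrored_groups.append((sym, members))

    # --- many:many ---------------------------------------------------------
    for _ in range(spec.n_many_many):
        s1 = mk.ref(mk.word().upper() + "1")
        s2 = mk.ref(mk.word().upper() + "2")
        base = normalize_symbol(s1)
        for j in range(1, spec.paralogs_per_group + 1):
            g = mk.gene(sp)
            mk.edge(g.gene_id, s1, "human",
                    mk.support(spec.min_tools + 2))
            mk.edge(g.gene_id, s2, "human",
                    mk.support(spec.min_tools, spec.min_tools + 1))
            plant(g, f"{base}.{j}", "paralog_suffix", "human_one_one",
                  suffix=str(j))

    # --- pseudoduplicate clusters ------------------------------------------
    flank = config.flank_bp
    for _ in range(spec.n_pseudodup_clusters):
        sym = mk.ref(mk.word().upper() + str(rng.randint(1, 9)))
        base = normalize_symbol(sym)
        members = []
        tie = mk.support()
        for _ in range(spec.cluster_size):
            g = mk.gene(sp)
            mk.edge(g.gene_id, sym, "human", tie)
            members.append(g)
        model_lens = {
            g.gene_id: g.length + 2 * flank for g in members
        }
        longest = max(model_lens.values())
        for a, b in zip(members, members[1:]):
            aln = int(round(longest * 0.95))
            aln = min(aln, max(model_lens[a.gene_id],
                               model_lens[b.gene_id]))
            for q, s in ((a, b), (b, a)):
                similarity_hits.append(
                    SimilarityHit(
                        query_id=q.gene_id,
                        subject_id=s.gene_id,
                        pct_identity=97.5,
                        aln_length=aln,
                        q_len=model_lens[q.gene_id],
                        s_len=model_lens[s.gene_id],
                    )
                )
        ordered = sorted((g.gene_id for g in members), key=str.lower)
        clusters_planted.append(ordered)
        for i, gid in enumerate(ordered):
            suf = letter_suffix(i)
            truth.per_gene[gid] = PlantedGene(
                gene_id=gid,
                species=sp,
                symbol=f"{base}.{suf}",
                rule="pseudodup_suffix",
                category="human_one_one",
                suffix=suf,
            )

    # --- vertebrate-only / invertebrate-only / orphans ---------------------
    for _ in range(spec.n_vertebrate_one_one):
        sym = mk.ref(mk.word().upper() + str(rng.randint(1, 9)),
                     taxon="other_vertebrate")
        g = mk.gene(sp, with_legacy=True)
        mk.edge(g.gene_id, sym, "other_vertebrate", mk.support())
        plant(g, f"loc{g.entrez_id}", "loc_fallback",
              "vertebrate_one_one")

    for i in range(spec.n_invertebrate_only):
        taxon = "invertebrate" if i % 2 == 0 else "non_animal"
        sym = mk.ref(mk.word().upper() + str(rng.randint(1, 9)),
                     taxon=taxon)
        g = mk.gene(sp)
        mk.edge(g.gene_id, sym, taxon, mk.support())
        plant(g, f"loc{g.entrez_id}", "loc_fallback", "invertebrate_only")

    for _ in range(spec.n_orphan):
        g = mk.gene(sp)
        plant(g, f"loc{g.entrez_id}", "loc_fallback", "unnameable")
        noise_candidates.append(g.gene_id)

    # --- sub-threshold noise pairs ------------------------------------------
    if spec.min_tools > 1:
        for i in range(spec.n_noise):
            sym = mk.ref(mk.word().upper() + str(rng.randint(1, 9)))
            gid = noise_candidates[i % len(noise_candidates)]
            mk.edge(gid, sym, "human", mk.support(1, spec.min_tools - 1))

    # --- optional mirrored species for suffix inheritance -------------------
    if spec.second_species:
        sp2 = spec.second_species
        if sp2 <= sp:
            raise ValueError(
                "second_species must sort after the primary species so "
                "suffix inheritance flows forward"
            )
        for sym, a_members in mirrored_groups:
            base = normalize_symbol(sym)
            partners = list(a_members)
            rng.shuffle(partners)
            for partner in partners:
                g = mk.gene(sp2)
                mk.edge(g.gene_id, sym, "human", mk.support())
                cross_links.append((g.gene_id, partner))
                inherited = truth.per_gene[partner].suffix
                plant(g, f"{base}.{inherited}", "paralog_suffix",
                      "human_one_one", suffix=inherited)

    calls_by_tool: dict[str, list[OrthologCall]] = {
        t: [] for t in spec.tool_panel
    }
    for call in mk.calls:
        calls_by_tool[call.tool].append(call)

    truth.params["clusters"] = clusters_planted
    return Cohort(
        genes=mk.genes,
        calls_by_tool=calls_by_tool,
        reference=mk.reference,
        overrides=overrides,
        cross_links=cross_links,
        similarity_hits=similarity_hits,
        legacy=mk.legacy,
        genome=mk.genome,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# sequence-level pseudoduplicate fixtures
# ---------------------------------------------------------------------------


@dataclass
class PseudodupTruth:
    """Per planted allele pair: divergence applied, realized identity, and
    whether the pair should cluster under the 90/90 defaults."""

    seed: int
    pairs: list[dict] = field(default_factory=list)
    #: gene_id -> exact gene-model sequence (model + flanks) planted
    sequences: dict[str, str] = field(default_factory=dict)


def _mutate(seq: str, divergence: float, rng: Random) -> tuple[str, int]:
    """Substitution-only mutation at the given per-base rate; returns the
    mutated sequence and the realized substitution count."""
    out = []
    n_sub = 0
    for base in seq:
        if rng.random() < divergence:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
            n_sub += 1
        else:
            out.append(base)
    return "".join(out), n_sub


def generate_pseudodup_sequences(
    seed: int,
    n_clusters: int = 3,
    divergence: float = 0.02,
    flank_bp: int = 1000,
    gene_length: int = 600,
    species: str = "spua",
) -> tuple[dict[str, str], list[GeneRecord], list[SimilarityHit], PseudodupTruth]:
    """Plant allele pairs: each pair is a gene model plus flanks copied and
    point-mutated at *divergence*, placed on its own contig.

    The emitted similarity hits carry the exact realized identity over the
    full model length (coverage 100%), so hit_passes reproduces the planted
    cluster labels analytically.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = Random(seed)
    genome: dict[str, str] = {}
    genes: list[GeneRecord] = []
    hits: list[SimilarityHit] = []
    truth = PseudodupTruth(seed=seed)
    entrez = 700000

    for i in range(1, n_clusters + 1):
        model_len = gene_length + 2 * flank_bp
        region = "".join(rng.choice("ACGT") for _ in range(model_len))
        mutated, n_sub = _mutate(region, divergence, rng)
        identity = (model_len - n_sub) / model_len * 100.0

        pair_ids = []
        for allele, seq in (("a", region), ("b", mutated)):
            entrez += rng.randint(1, 9)
            gid = f"{species}pd{i:02d}{allele}"
            chrom = f"{species}pdctg{i:02d}{allele}"
            genome[chrom] = seq
            start = flank_bp + 1
            end = flank_bp + gene_length
            genes.append(
                GeneRecord(
                    species=species,
                    gene_id=gid,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+",
                    exons=[(start, start + gene_length // 3),
                           (start + gene_length // 2, end)],
                    entrez_id=entrez,
                    product=f"hypothetical protein {entrez}",
                )
            )
            truth.sequences[gid] = seq
            pair_ids.append(gid)

        q, s = pair_ids
        for a, b in ((q, s), (s, q)):
            hits.append(
                SimilarityHit(
                    query_id=a,
                    subject_id=b,
                    pct_identity=identity,
                    aln_length=model_len,
                    q_len=model_len,
                    s_len=model_len,
                )
            )
        truth.pairs.append(
            {
                "members": pair_ids,
                "divergence": divergence,
                "identity": identity,
                "in_cluster": identity >= 90.0,
            }
        )
    return genome, genes, hits, truth
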
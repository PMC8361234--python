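"""Consensus orthology: aggregate per-tool calls into supported edges,
classify orthology-group topology, and bucket genes into nameability
categories.

A gene pair is *supported* when at least ``min_tools`` distinct tools
reported it (the threshold is inclusive).  Only supported edges take part in
topology classification; weaker edges never merge groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import OrthologCall

TOPOLOGIES = ("one_one", "one_many", "many_one", "many_many", "orphan")
CATEGORIES = (
    "human_one_one",
    "vertebrate_one_one",
    "invertebrate_only",
    "unnameable",
)


@dataclass
class NomenclatureConfig:
    """All pipeline thresholds in one place.

    Defaults encode the standard guideline values: >=3 distinct tools for consensus
    support, the 90/90 identity/coverage rule for pseudoduplicates, and
    1 kb of flanking sequence around each gene model.
    """

    min_tools: int = 3
    identity_threshold: float = 90.0
    coverage_threshold: float = 90.0
    flank_bp: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_tools < 1:
            raise ValueError("min_tools must be >= 1")
        for name in ("identity_threshold", "coverage_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass(frozen=True)
class ConsensusEdge:
    query_id: str
    subject_id: str
    subject_taxon: str
    support_count: int
    supported: bool

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError("support_count must be >= 1")


@dataclass
class OrthologyGroup:
    echino_members: set[str]
    ref_members: set[str]
    topology: str
    edge_support: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"bad topology {self.topology!r}")


def tally_support(
    calls: Iterable[OrthologCall], config: NomenclatureConfig
) -> list[ConsensusEdge]:
    """Collapse per-tool calls into one edge per (query, subject) pair.

    support_count counts *distinct tools*, never rows: one tool contributes
    at most one unit of support per pair.  The same subject reported with
    two different taxa is a hard error.
    """
    tools_by_pair: dict[tuple[str, str], set[str]] = {}
    taxon_of: dict[str, str] = {}
    for call in calls:
        prev = taxon_of.setdefault(call.subject_id, call.subject_taxon)
        if prev != call.subject_taxon:
            raise ValueError(
                f"subject {call.subject_id!r} reported with conflicting "
                f"taxa {prev!r} and {call.subject_taxon!r}"
            )
        tools_by_pair.setdefault(
            (call.query_id, call.subject_id), set()
        ).add(call.tool)
    edges = [
        ConsensusEdge(
            query_id=q,
            subject_id=s,
            subject_taxon=taxon_of[s],
            support_count=len(tools),
            supported=len(tools) >= config.min_tools,
        )
        for (q, s), tools in tools_by_pair.items()
    ]
    edges.sort(key=lambda e: (e.query_id, e.subject_id))
    return edges


def classify_topology(
    edges: Sequence[ConsensusEdge],
    all_gene_ids: Iterable[str] | None = None,
) -> list[OrthologyGroup]:
    """Partition the supported-edge bipartite graph into connected
    components and label each by its shape.

    Genes named in *all_gene_ids* (or appearing only in unsupported edges)
    that end up with no supported edge are returned as singleton ``orphan``
    groups, so every gene flows through the naming cascade exactly once.
    """
    graph = nx.Graph()
    support: dict[tuple[str, str], int] = {}
    gene_ids = set(all_gene_ids or ())
    for e in edges:
        gene_ids.add(e.query_id)
        if not e.supported:
            continue
        graph.add_edge(("g", e.query_id), ("r", e.subject_id))
        support[(e.query_id, e.subject_id)] = e.support_count

    groups: list[OrthologyGroup] = []
    for comp in nx.connected_components(graph):
        echino = {n[1] for n in comp if n[0] == "g"}
        refs = {n[1] for n in comp if n[0] == "r"}
        if len(echino) == 1 and len(refs) == 1:
            topo = "one_one"
        elif len(echino) == 1:
            topo = "one_many"
        elif len(refs) == 1:
            topo = "many_one"
        else:
            topo = "many_many"
        groups.append(
            OrthologyGroup(
                echino_members=echino,
                ref_members=refs,
                topology=topo,
                edge_support={
                    (g, r): support[(g, r)]
                    for g in echino
                    for r in refs
                    if (g, r) in support
                },
            )
        )
    connected = {g for grp in groups for g in grp.echino_members}
    for gid in sorted(gene_ids - connected):
        groups.append(
            OrthologyGroup(
                echino_members={gid}, ref_members=set(), topology="orphan"
            )
        )
    groups.sort(key=lambda g: min(g.echino_members))
    return groups


def stratum_edges(
    edges: Sequence[ConsensusEdge], taxa: Iterable[str]
) -> list[ConsensusEdge]:
    """Supported edges restricted to subjects of the given taxa."""
    wanted = set(taxa)
    return [e for e in edges if e.supported and e.subject_taxon in wanted]


def categorize_genes(
    edges: Sequence[ConsensusEdge],
    all_gene_ids: Iterable[str],
    config: NomenclatureConfig | None = None,
) -> dict[str, str]:
    """Bucket every gene into a nameability category.

    Topology is evaluated separately per reference-taxon stratum; human
    orthology takes precedence over other-vertebrate one:one orthology,
    which takes precedence over invertebrate/non-animal orthologs.  Genes
    with no supported edge at all are ``unnameable``.

    ``human_one_one`` is claimed by any gene whose naming is informed by
    human orthology; in the (rare) non-one:one human strata the label is
    kept for totality of the mapping.
    """
    gene_ids = set(all_gene_ids)
    human = stratum_edges(edges, ("human",))
    vert = stratum_edges(edges, ("other_vertebrate",))
    any_supported = {e.query_id for e in edges if e.supported}

    human_genes = {e.query_id for e in human}
    vert_topology: dict[str, str] = {}
    for grp in classify_topology(vert):
        for gid in grp.echino_members:
            vert_topology[gid] = grp.topology

    invert_only: set[str] = set()
    for gid in any_supported:
        taxa = {
            e.subject_taxon
            for e in edges
            if e.supported and e.query_id == gid
        }
        if taxa <= {"invertebrate", "non_animal"}:
            invert_only.add(gid)

    out: dict[str, str] = {}
    for gid in gene_ids | any_supported:
        if gid in human_genes:
            out[gid] = "human_one_one"
        elif vert_topology.get(gid) == "one_one":
            out[gid] = "vertebrate_one_one"
        elif gid in invert_only:
            out[gid] = "invertebrate_only"
        else:
            out[gid] = "unnameable"
    return out


def write_edge_table(path, edges: Sequence[ConsensusEdge]) -> None:
    from .io_formats import _write_tsv

    rows = [
        (e.query_id, e.subject_id, e.subject_taxon, e.support_count,
         int(e.supported))
        for e in sorted(edges, key=lambda e: (e.query_id, e.subject_id))
    ]
    _write_tsv(
        path, ("query", "subject", "taxon", "support", "supported"), rows
    )


def read_edge_table(path) -> list[ConsensusEdge]:
    from .io_formats import _open_tsv, _require_columns

    header, rows = _open_tsv(path)
    idx = _require_columns(
        header, ("query", "subject", "taxon", "support", "supported"), path
    )
    return [
        ConsensusEdge(
            query_id=row[idx["query"]],
            subject_id=row[idx["subject"]],
            subject_taxon=row[idx["taxon"]],
            support_count=int(row[idx["support"]]),
            supported=bool(int(row[idx["supported"]])),
        )
        for _, row in rows
    ]


def write_group_table(path, groups: Sequence[OrthologyGroup]) -> None:
    from .io_formats import _write_tsv

    rows = []
    for i, grp in enumerate(
        sorted(groups, key=lambda g: min(g.echino_members)), 1
    ):
        rows.append(
            (
                f"OG{i:05d}",
                grp.topology,
                ";".join(sorted(grp.echino_members)),
                ";".join(sorted(grp.ref_members)),
            )
        )
    _write_tsv(path, ("group_id", "topology", "genes", "refs"), rows)
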
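"""Symbol/name assignment: the nomenclature decision cascade.

Every gene receives exactly one :class:`Assignment` through one of the
rules below, dispatched on pseudoduplicate-cluster membership first and
human-stratum orthology topology second:

* ``one_one`` — the human identifier is adopted directly;
* ``one_many_support`` / ``one_many_stem`` / ``one_many_curator`` /
  ``one_many_alpha`` — tie-breaking cascade over multiple human candidates;
* ``pseudodup_suffix`` — cluster members share a base symbol with ``.a``,
  ``.b``, ... letter suffixes (species-local, no orthology meaning);
* ``paralog_suffix`` — lineage expansions share a base symbol with ``.1``,
  ``.2``, ... suffixes, kept equal across species where cross-species
  one:one links allow;
* ``loc_fallback`` — no qualifying human ortholog: ``loc`` + Entrez ID.

Symbols are lowercase machine-readable strings; Greek letters and Roman
numerals in source identifiers are converted to Latin letters and Arabic
digits.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .consensus import (
    ConsensusEdge,
    NomenclatureConfig,
    OrthologyGroup,
    classify_topology,
    stratum_edges,
)
from .io_formats import GeneRecord, ReferenceGene
from .pseudodup import PseudodupCluster

log = logging.getLogger(__name__)

RULES = (
    "one_one",
    "one_many_support",
    "one_many_stem",
    "one_many_curator",
    "one_many_alpha",
    "pseudodup_suffix",
    "paralog_suffix",
    "loc_fallback",
)

#: an emitted symbol: lowercase letters + digits, "." and "-" separators
SYMBOL_PATTERN = re.compile(r"^[a-z0-9][a-z0-9.\-]*$")

# Greek -> single Latin letter transliteration table (both cases).
GREEK_LETTERS = {
    "α": "a", "β": "b", "γ": "g", "δ": "d", "ε": "e", "ζ": "z",
    "η": "h", "θ": "t", "ι": "i", "κ": "k", "λ": "l", "μ": "m",
    "ν": "n", "ξ": "x", "ο": "o", "π": "p", "ρ": "r", "σ": "s",
    "ς": "s", "τ": "t", "υ": "u", "φ": "f", "χ": "c", "ψ": "y",
    "ω": "w",
}
GREEK_LETTERS.update(
    {k.upper(): v for k, v in list(GREEK_LETTERS.items()) if k != "ς"}
)

GREEK_WORDS = {
    "alpha": "a", "beta": "b", "gamma": "g", "delta": "d",
    "epsilon": "e", "zeta": "z", "eta": "h", "theta": "t",
    "iota": "i", "kappa": "k", "lambda": "l", "mu": "m", "nu": "n",
    "xi": "x", "omicron": "o", "pi": "p", "rho": "r", "sigma": "s",
    "tau": "t", "upsilon": "u", "phi": "f", "chi": "c", "psi": "y",
    "omega": "w",
}

_ROMAN_MAX = 20


def _canonical_roman(n: int) -> str:
    out = []
    for value, numeral in ((10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")):
        while n >= value:
            out.append(numeral)
            n -= value
    return "".join(out)


_ROMAN_TABLE = {_canonical_roman(n): n for n in range(1, _ROMAN_MAX + 1)}


def roman_to_arabic(token: str) -> int | None:
    """Convert a canonical Roman numeral (1-20) to an integer.

    Non-canonical forms ("IIII") and non-numeral tokens return None;
    no-conversion is a valid outcome, never an error.
    """
    return _ROMAN_TABLE.get(token.upper())


def _normalize_once(s: str) -> str:
    s = unicodedata.normalize("NFC", s)
    s = "".join(GREEK_LETTERS.get(ch, ch) for ch in s)
    s = s.lower()
    s = re.sub(r"[^a-z0-9.\s_\-]", "-", s)
    tokens = [t for t in re.split(r"[\s_\-]+", s) if t]

    tail: list[str] = []
    while tokens:
        t = tokens[-1]
        arabic = roman_to_arabic(t)
        if arabic is not None:
            tail.append(str(arabic))
            tokens.pop()
            continue
        if t in GREEK_WORDS:
            tail.append(GREEK_WORDS[t])
            tokens.pop()
            continue
        break
    tail.reverse()
    return ("-".join(tokens) + "".join(tail)).strip(".-")


def normalize_symbol(raw: str) -> str:
    """Produce the machine-readable form of a gene symbol.

    Unicode Greek letters become single Latin letters anywhere in the
    string; spelled-out Greek tokens and Roman-numeral tokens are converted
    only when they are standalone trailing tokens (and are then joined to
    the stem without a separator).  The result is lowercase with whitespace
    and disallowed characters mapped to "-".

    A single pass is applied to fixpoint (stripping separators can expose
    a new trailing token, e.g. "iv." -> "iv" -> "4"), which makes the
    operation idempotent.
    """
    if not raw:
        raise ValueError("cannot normalize an empty symbol")
    prev = raw
    for _ in range(len(raw) + 2):
        cur = _normalize_once(prev)
        if not cur:
            raise ValueError(
                f"symbol {raw!r} normalizes to the empty string"
            )
        if cur == prev:
            return cur
        prev = cur
    return prev


@dataclass
class Assignment:
    """The final identifier for one gene plus full rule provenance."""

    gene_id: str
    species: str
    symbol: str
    full_name: str
    rule_fired: str
    chosen_ortholog: str | None = None
    support_count: int | None = None
    pseudodup_cluster: str | None = None
    suffix: str | None = None
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rule_fired not in RULES:
            raise ValueError(f"unknown rule {self.rule_fired!r}")
        if not SYMBOL_PATTERN.match(self.symbol):
            raise ValueError(f"symbol {self.symbol!r} is not machine-readable")
        if self.rule_fired == "loc_fallback" and not re.match(
            r"^loc\d+", self.symbol
        ):
            raise ValueError(
                f"loc_fallback symbol {self.symbol!r} must be loc<entrez>"
            )


@dataclass(frozen=True)
class CuratorOverride:
    gene_id: str
    forced_symbol: str
    forced_name: str
    note: str = ""

    def __post_init__(self) -> None:
        if normalize_symbol(self.forced_symbol) != self.forced_symbol:
            raise ValueError(
                f"override symbol {self.forced_symbol!r} is not in "
                "normalized form"
            )


def family_stem(ref: ReferenceGene) -> str | None:
    """The family stem: from the reference table when given, else derived
    by stripping trailing Arabic digits from the normalized symbol."""
    if ref.family_stem:
        return normalize_symbol(ref.family_stem)
    derived = re.sub(r"\d+$", "", normalize_symbol(ref.symbol))
    return derived.strip(".-") or None


def assign_one_to_one(
    group: OrthologyGroup,
    reference: Mapping[str, ReferenceGene],
    gene: GeneRecord,
) -> Assignment:
    """one:one with a human gene: adopt the human identifier outright."""
    (symbol,) = group.ref_members
    (gid,) = group.echino_members
    if symbol not in reference:
        raise KeyError(f"reference symbol {symbol!r} not in reference table")
    ref = reference[symbol]
    return Assignment(
        gene_id=gid,
        species=gene.species,
        symbol=normalize_symbol(symbol),
        full_name=ref.full_name,
        rule_fired="one_one",
        chosen_ortholog=symbol,
        support_count=group.edge_support.get((gid, symbol)),
        synonyms=list(gene.legacy_ids),
    )


def choose_ortholog(
    group: OrthologyGroup,
    reference: Mapping[str, ReferenceGene],
    overrides: Mapping[str, CuratorOverride] | None = None,
    family_species: Mapping[str, set[str]] | None = None,
    species: str = "",
) -> tuple[str, str]:
    """Resolve a one:many group to a single identifier.

    Cascade: (1) unique maximum tool support wins; (2) a full-tie whose
    candidates all share one family stem — and whose family shows no
    orthology to another input species' gene — is named with the stem
    itself; (3) a curator override; (4) the first candidate in
    case-insensitive lexicographic order of normalized symbols.

    Returns (identifier, rule); the identifier is a reference symbol for
    rules 1/4, a stem for rule 2, a forced symbol for rule 3.
    """
    (gid,) = group.echino_members
    candidates = sorted(group.ref_members)
    if len(candidates) < 2:
        raise ValueError("choose_ortholog needs >= 2 candidates")
    support = {c: group.edge_support.get((gid, c), 0) for c in candidates}
    top = max(support.values())
    tied = sorted(c for c in candidates if support[c] == top)
    if len(tied) == 1:
        return tied[0], "one_many_support"

    stems = {
        family_stem(reference[c]) if c in reference else None for c in tied
    }
    if len(stems) == 1 and None not in stems:
        (stem,) = stems
        other_species = (family_species or {}).get(stem, set()) - {species}
        if not other_species:
            return stem, "one_many_stem"

    if overrides and gid in overrides:
        ov = overrides[gid]
        return ov.forced_symbol, "one_many_curator"

    winner = min(tied, key=lambda c: normalize_symbol(c))
    return winner, "one_many_alpha"


def letter_suffix(index: int) -> str:
    """0 -> a, 1 -> b, ... 25 -> z, 26 -> aa, 27 -> ab (bijective base 26)."""
    if index < 0:
        raise ValueError("index must be >= 0")
    out = []
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        out.append(chr(ord("a") + rem))
    return "".join(reversed(out))


def assign_pseudodup_suffixes(
    cluster: PseudodupCluster,
    base_symbol: str,
    species: str,
    genes: Mapping[str, GeneRecord],
    base_name: str = "",
    chosen_ortholog: str | None = None,
    cluster_id: str | None = None,
    support: Mapping[str, int] | None = None,
) -> list[Assignment]:
    """Letter-suffix every cluster member: base.a, base.b, ... aa after z.

    Members are ordered case-insensitively by gene_id; the letters carry no
    orthology information and are independent between species.
    """
    if len(cluster.members) < 2:
        raise ValueError("not a cluster: size < 2")
    members = sorted(cluster.members, key=str.lower)
    out = []
    for i, gid in enumerate(members):
        suffix = letter_suffix(i)
        gene = genes[gid]
        out.append(
            Assignment(
                gene_id=gid,
                species=species,
                symbol=f"{base_symbol}.{suffix}",
                full_name=base_name,
                rule_fired="pseudodup_suffix",
                chosen_ortholog=chosen_ortholog,
                support_count=(support or {}).get(gid),
                pseudodup_cluster=cluster_id,
                suffix=suffix,
                synonyms=list(gene.legacy_ids),
            )
        )
    return out


def assign_paralog_suffixes(
    group: OrthologyGroup,
    base_symbol: str,
    species: str,
    genes: Mapping[str, GeneRecord],
    base_name: str = "",
    chosen_ortholog: str | None = None,
    inherited: Mapping[str, int] | None = None,
    support: Mapping[str, int] | None = None,
) -> list[Assignment]:
    """Number-suffix a many:one / many:many expansion: base.1, base.2, ...

    A member with a supported one:one cross-species link to an
    already-suffixed ortholog inherits that number (*inherited*); when two
    members claim the same number both deterministically fall back to fresh
    numbers (logged).  Remaining members take the lowest unused numbers in
    gene_id sort order.
    """
    members = sorted(group.echino_members, key=str.lower)
    inherited = dict(inherited or {})

    claims: dict[int, list[str]] = {}
    for gid, num in inherited.items():
        claims.setdefault(num, []).append(gid)
    for num, claimants in sorted(claims.items()):
        if len(claimants) > 1:
            log.warning(
                "suffix inheritance conflict on %s.%d between %s; "
                "assigning fresh numbers",
                base_symbol, num, ", ".join(sorted(claimants)),
            )
            for gid in claimants:
                del inherited[gid]

    numbers: dict[str, int] = {
        gid: num for gid, num in inherited.items() if gid in set(members)
    }
    used = set(numbers.values())
    nxt = 1
    for gid in members:
        if gid in numbers:
            continue
        while nxt in used:
            nxt += 1
        numbers[gid] = nxt
        used.add(nxt)

    out = []
    for gid in members:
        num = numbers[gid]
        out.append(
            Assignment(
                gene_id=gid,
                species=species,
                symbol=f"{base_symbol}.{num}",
                full_name=base_name,
                rule_fired="paralog_suffix",
                chosen_ortholog=chosen_ortholog,
                support_count=(support or {}).get(gid),
                suffix=str(num),
                synonyms=list(genes[gid].legacy_ids),
            )
        )
    return out


def loc_fallback(gene: GeneRecord) -> Assignment:
    """No qualifying ortholog: keep the annotation identifier, lowercased
    to loc<entrez>; the uppercase NCBI form joins the synonyms."""
    if gene.entrez_id is None:
        raise ValueError(
            f"{gene.gene_id}: loc_fallback requires an Entrez ID; supply "
            "one via the gene model annotation (Dbxref=GeneID:...)"
        )
    ncbi_form = f"LOC{gene.entrez_id}"
    synonyms = [ncbi_form] + [
        lid for lid in gene.legacy_ids if lid != ncbi_form
    ]
    return Assignment(
        gene_id=gene.gene_id,
        species=gene.species,
        symbol=f"loc{gene.entrez_id}",
        full_name=gene.product or "uncharacterized protein",
        rule_fired="loc_fallback",
        synonyms=synonyms,
    )


def render_with_previous(assignment: Assignment) -> str:
    """Display form "current (previous)"; the most recent legacy symbol is
    the last synonym."""
    if assignment.synonyms:
        return f"{assignment.symbol} ({assignment.synonyms[-1]})"
    return assignment.symbol


# ---------------------------------------------------------------------------
# whole-cohort driver
# ---------------------------------------------------------------------------


def _resolve_base(
    candidate_support: Mapping[str, int],
    reference: Mapping[str, ReferenceGene],
) -> str:
    """Base-symbol resolution for multi-gene groups and clusters: highest
    tool support, ties broken alphanumerically on the normalized symbol."""
    top = max(candidate_support.values())
    tied = [c for c, n in candidate_support.items() if n == top]
    return min(tied, key=lambda c: normalize_symbol(c))


def _family_species_map(
    edges_by_species: Mapping[str, Sequence[ConsensusEdge]],
    reference: Mapping[str, ReferenceGene],
) -> dict[str, set[str]]:
    """stem -> set of species with a supported edge to any family member."""
    out: dict[str, set[str]] = {}
    for species, edges in edges_by_species.items():
        for e in edges:
            if not e.supported or e.subject_id not in reference:
                continue
            stem = family_stem(reference[e.subject_id])
            if stem:
                out.setdefault(stem, set()).add(species)
    return out


def assign_identifiers(
    genes: Sequence[GeneRecord],
    edges: Sequence[ConsensusEdge],
    clusters: Sequence[PseudodupCluster],
    reference: Mapping[str, ReferenceGene],
    overrides: Mapping[str, CuratorOverride] | None = None,
    cross_links: Iterable[tuple[str, str]] | None = None,
    config: NomenclatureConfig | None = None,
) -> list[Assignment]:
    """Run the full decision cascade over a (possibly multi-species) cohort.

    Per gene: pseudoduplicate-cluster membership wins first; otherwise the
    human-stratum orthology topology dispatches to the one:one rule, the
    one:many cascade, paralog suffixing, or the loc fallback.  Species are
    processed in sorted order so cross-species suffix inheritance is
    deterministic; species-wide symbol uniqueness is enforced at the end
    with numeric disambiguation plus a logged warning.
    """
    config = config or NomenclatureConfig()
    overrides = overrides or {}
    genes_by_id = {g.gene_id: g for g in genes}
    species_of = {g.gene_id: g.species for g in genes}
    all_species = sorted({g.species for g in genes})

    for e in edges:
        if e.supported and e.query_id not in genes_by_id:
            raise KeyError(f"edge references unknown gene {e.query_id!r}")

    edges_by_species: dict[str, list[ConsensusEdge]] = {
        sp: [] for sp in all_species
    }
    for e in edges:
        sp = species_of.get(e.query_id)
        if sp is not None:
            edges_by_species[sp].append(e)
    fam_species = _family_species_map(edges_by_species, reference)

    cluster_of: dict[str, tuple[str, PseudodupCluster]] = {}
    for i, cl in enumerate(
        sorted(clusters, key=lambda c: c.members[0]), 1
    ):
        cid = f"PD{i:04d}"
        for gid in cl.members:
            cluster_of[gid] = (cid, cl)

    links: dict[str, set[str]] = {}
    for a, b in cross_links or ():
        links.setdefault(a, set()).add(b)
        links.setdefault(b, set()).add(a)

    # registry of already-suffixed paralogs: gene_id -> (base, number)
    suffix_registry: dict[str, tuple[str, int]] = {}
    assignments: list[Assignment] = []

    for species in all_species:
        sp_genes = {
            gid: g for gid, g in genes_by_id.items() if g.species == species
        }
        human_edges = stratum_edges(edges_by_species[species], ("human",))
        support_of: dict[str, dict[str, int]] = {}
        for e in human_edges:
            support_of.setdefault(e.query_id, {})[e.subject_id] = (
                e.support_count
            )
        groups = classify_topology(human_edges, sp_genes)

        handled_clusters: set[str] = set()
        for grp in groups:
            members = sorted(grp.echino_members)

            in_cluster = [g for g in members if g in cluster_of]
            if in_cluster:
                for gid in in_cluster:
                    cid, cl = cluster_of[gid]
                    if cid in handled_clusters:
                        continue
                    handled_clusters.add(cid)
                    assignments.extend(
                        _assign_cluster(
                            cid, cl, support_of, reference, sp_genes, species
                        )
                    )
                members = [g for g in members if g not in cluster_of]
                if not members:
                    continue
                # remaining (non-cluster) members re-dispatch on their
                # residual shape within the group
                grp = OrthologyGroup(
                    echino_members=set(members),
                    ref_members=set(grp.ref_members),
                    topology=_retopology(len(members), len(grp.ref_members)),
                    edge_support={
                        k: v
                        for k, v in grp.edge_support.items()
                        if k[0] in members
                    },
                )

            if grp.topology == "orphan":
                for gid in members:
                    assignments.append(loc_fallback(sp_genes[gid]))
            elif grp.topology == "one_one":
                assignments.append(
                    assign_one_to_one(grp, reference, sp_genes[members[0]])
                )
            elif grp.topology == "one_many":
                gid = members[0]
                ident, rule = choose_ortholog(
                    grp, reference, overrides, fam_species, species
                )
                assignments.append(
                    _one_many_assignment(
                        gid, species, ident, rule, grp, reference,
                        overrides, sp_genes,
                    )
                )
            else:  # many_one / many_many
                cand_support: dict[str, int] = {}
                for (gid, sym), n in grp.edge_support.items():
                    cand_support[sym] = max(cand_support.get(sym, 0), n)
                base_ref = _resolve_base(cand_support, reference)
                base = normalize_symbol(base_ref)
                base_name = (
                    reference[base_ref].full_name
                    if base_ref in reference
                    else base_ref
                )
                inherited: dict[str, int] = {}
                for gid in members:
                    for other in sorted(links.get(gid, ())):
                        reg = suffix_registry.get(other)
                        if reg and reg[0] == base and (
                            species_of.get(other) != species
                        ):
                            inherited[gid] = reg[1]
                            break
                per_gene_support = {
                    gid: grp.edge_support.get((gid, base_ref))
                    for gid in members
                }
                new = assign_paralog_suffixes(
                    grp, base, species, sp_genes,
                    base_name=base_name,
                    chosen_ortholog=base_ref,
                    inherited=inherited,
                    support={
                        g: n for g, n in per_gene_support.items()
                        if n is not None
                    },
                )
                for a in new:
                    suffix_registry[a.gene_id] = (base, int(a.suffix))
                assignments.extend(new)

    assignments = _enforce_unique_symbols(assignments)
    assignments.sort(key=lambda a: (a.species, a.gene_id))
    assigned = {a.gene_id for a in assignments}
    missing = set(genes_by_id) - assigned
    if missing or len(assignments) != len(genes_by_id):
        raise RuntimeError(
            f"assignment incomplete: missing {sorted(missing)[:5]}..."
            if missing
            else "duplicate assignments detected"
        )
    return assignments


def _retopology(n_genes: int, n_refs: int) -> str:
    if n_refs == 0:
        return "orphan"
    if n_genes == 1:
        return "one_one" if n_refs == 1 else "one_many"
    return "many_one" if n_refs == 1 else "many_many"


def _one_many_assignment(
    gid, species, ident, rule, grp, reference, overrides, sp_genes
) -> Assignment:
    gene = sp_genes[gid]
    if rule == "one_many_curator":
        ov = overrides[gid]
        return Assignment(
            gene_id=gid,
            species=species,
            symbol=ov.forced_symbol,
            full_name=ov.forced_name,
            rule_fired=rule,
            chosen_ortholog=None,
            synonyms=list(gene.legacy_ids),
        )
    if rule == "one_many_stem":
        return Assignment(
            gene_id=gid,
            species=species,
            symbol=ident,
            full_name=f"{ident} family",
            rule_fired=rule,
            chosen_ortholog=None,
            synonyms=list(gene.legacy_ids),
        )
    ref = reference[ident]
    return Assignment(
        gene_id=gid,
        species=species,
        symbol=normalize_symbol(ident),
        full_name=ref.full_name,
        rule_fired=rule,
        chosen_ortholog=ident,
        support_count=grp.edge_support.get((gid, ident)),
        synonyms=list(gene.legacy_ids),
    )


def _assign_cluster(
    cid: str,
    cluster: PseudodupCluster,
    support_of: Mapping[str, Mapping[str, int]],
    reference: Mapping[str, ReferenceGene],
    sp_genes: Mapping[str, GeneRecord],
    species: str,
) -> list[Assignment]:
    """Resolve one pseudoduplicate cluster: pick the consensus ortholog
    over all members' supported human edges, then letter-suffix.  A cluster
    with no supported human edge falls back to per-gene loc symbols."""
    members = [g for g in cluster.members if g in sp_genes]
    cand_support: dict[str, int] = {}
    for gid in members:
        for sym, n in support_of.get(gid, {}).items():
            cand_support[sym] = max(cand_support.get(sym, 0), n)
    if not cand_support:
        return [loc_fallback(sp_genes[g]) for g in sorted(members)]
    base_ref = _resolve_base(cand_support, reference)
    base = normalize_symbol(base_ref)
    base_name = (
        reference[base_ref].full_name if base_ref in reference else base_ref
    )
    per_gene = {
        gid: support_of.get(gid, {}).get(base_ref) for gid in members
    }
    return assign_pseudodup_suffixes(
        PseudodupCluster(members=members, evidence=cluster.evidence),
        base,
        species,
        sp_genes,
        base_name=base_name,
        chosen_ortholog=base_ref,
        cluster_id=cid,
        support={g: n for g, n in per_gene.items() if n is not None},
    )


def _enforce_unique_symbols(
    assignments: list[Assignment],
) -> list[Assignment]:
    """Last-resort collision handling: deterministic numeric disambiguation
    ("sym", "sym-2", "sym-3", ...) in (species, gene_id) order."""
    used: set[tuple[str, str]] = set()
    out = []
    for a in sorted(assignments, key=lambda a: (a.species, a.gene_id)):
        key = (a.species, a.symbol)
        if key in used:
            n = 2
            while (a.species, f"{a.symbol}-{n}") in used:
                n += 1
            log.warning(
                "symbol collision in %s: %s renamed to %s-%d",
                a.species, a.symbol, a.symbol, n,
            )
            a.symbol = f"{a.symbol}-{n}"
        used.add((a.species, a.symbol))
        out.append(a)
    return out
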
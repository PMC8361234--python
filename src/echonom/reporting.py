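"""Cohort-level category statistics.

Counts and shares of nameable genes per category (human one:one,
other-vertebrate one:one, invertebrate/non-animal only), each share
expressed both as a fraction of nameable genes and of all protein-coding
genes, with half-up rounding at a per-call precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

_COUNT_CATEGORIES = (
    "human_one_one",
    "vertebrate_one_one",
    "invertebrate_only",
)


def format_percentage(numerator: int, denominator: int, decimals: int) -> str:
    """Render numerator/denominator as a percent string with half-up
    rounding at *decimals* places, e.g. (964, 8066, 0) -> "12%"."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if numerator < 0 or decimals < 0:
        raise ValueError("numerator and decimals must be >= 0")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return f"{value.quantize(quantum, rounding=ROUND_HALF_UP)}%"


@dataclass
class CategoryStats:
    n_total_protein_coding: int
    n_nameable: int
    n_human_one_one: int
    n_vertebrate_one_one: int
    n_invertebrate_only: int
    #: category -> {"of_nameable": fraction, "of_total": fraction,
    #:              "of_nameable_fmt": {dp: str}, "of_total_fmt": {dp: str}}
    percentages: dict[str, dict]

    def __post_init__(self) -> None:
        named = (
            self.n_human_one_one
            + self.n_vertebrate_one_one
            + self.n_invertebrate_only
        )
        if not named <= self.n_nameable <= self.n_total_protein_coding:
            raise ValueError(
                "counts violate category <= nameable <= total ordering"
            )

    def share(self, category: str, of: str = "nameable") -> Fraction:
        return self.percentages[category][f"of_{of}"]

    def formatted(self, category: str, of: str, decimals: int) -> str:
        count = getattr(self, f"n_{category}")
        denom = (
            self.n_nameable if of == "nameable"
            else self.n_total_protein_coding
        )
        return format_percentage(count, denom, decimals)


def compute_category_stats(
    categories: Mapping[str, str] | None = None,
    n_total: int = 0,
    *,
    n_human_one_one: int | None = None,
    n_vertebrate_one_one: int | None = None,
    n_invertebrate_only: int | None = None,
    n_nameable: int | None = None,
) -> CategoryStats:
    """Tally category counts (from a gene_id -> category mapping, or from
    explicit counts) and compute both shares for each category.

    ``n_nameable`` defaults to the sum of the three named categories.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if categories is not None:
        tally = {c: 0 for c in _COUNT_CATEGORIES}
        for cat in categories.values():
            if cat in tally:
                tally[cat] += 1
        n_human_one_one = tally["human_one_one"]
        n_vertebrate_one_one = tally["vertebrate_one_one"]
        n_invertebrate_only = tally["invertebrate_only"]
    counts = {
        "human_one_one": n_human_one_one or 0,
        "vertebrate_one_one": n_vertebrate_one_one or 0,
        "invertebrate_only": n_invertebrate_only or 0,
    }
    nameable = (
        n_nameable if n_nameable is not None else sum(counts.values())
    )
    if nameable <= 0:
        raise ValueError("no nameable genes")
    percentages = {}
    for cat, n in counts.items():
        percentages[cat] = {
            "of_nameable": Fraction(n, nameable),
            "of_total": Fraction(n, n_total),
            "of_nameable_fmt": {
                dp: format_percentage(n, nameable, dp) for dp in (0, 1, 2)
            },
            "of_total_fmt": {
                dp: format_percentage(n, n_total, dp) for dp in (0, 1, 2)
            },
        }
    return CategoryStats(
        n_total_protein_coding=n_total,
        n_nameable=nameable,
        n_human_one_one=counts["human_one_one"],
        n_vertebrate_one_one=counts["vertebrate_one_one"],
        n_invertebrate_only=counts["invertebrate_only"],
        percentages=percentages,
    )


def render_stats_table(stats: CategoryStats) -> str:
    """Tab-separated stats block (category, count, shares at 0/1/2 dp)."""
    lines = [
        "category\tcount\tof_nameable_0dp\tof_nameable_1dp\tof_nameable_2dp"
        "\tof_total_0dp\tof_total_1dp\tof_total_2dp"
    ]
    for cat in _COUNT_CATEGORIES:
        p = stats.percentages[cat]
        lines.append(
            "\t".join(
                [
                    cat,
                    str(getattr(stats, f"n_{cat}")),
                    p["of_nameable_fmt"][0],
                    p["of_nameable_fmt"][1],
                    p["of_nameable_fmt"][2],
                    p["of_total_fmt"][0],
                    p["of_total_fmt"][1],
                    p["of_total_fmt"][2],
                ]
            )
        )
    lines.append(
        f"nameable\t{stats.n_nameable}\t-\t-\t-\t"
        + "\t".join(
            format_percentage(stats.n_nameable, stats.n_total_protein_coding, dp)
            for dp in (0, 1, 2)
        )
    )
    lines.append(f"total_protein_coding\t{stats.n_total_protein_coding}"
                 "\t-\t-\t-\t-\t-\t-")
    return "\n".join(lines) + "\n"


def render_stats_text(stats: CategoryStats) -> str:
    """Human-readable summary block."""
    return (
        f"Of {stats.n_nameable} nameable genes "
        f"({stats.n_total_protein_coding} protein-coding genes in total):\n"
        f"  {stats.formatted('human_one_one', 'nameable', 2)} "
        f"({stats.n_human_one_one}) have human one:one orthologs "
        f"({stats.formatted('human_one_one', 'total', 1)} of all genes)\n"
        f"  {stats.formatted('vertebrate_one_one', 'nameable', 1)} "
        f"({stats.n_vertebrate_one_one}) have only other-vertebrate one:one "
        f"orthologs ({stats.formatted('vertebrate_one_one', 'total', 2)} "
        f"of all genes)\n"
        f"  {stats.formatted('invertebrate_only', 'nameable', 0)} "
        f"({stats.n_invertebrate_only}) have only invertebrate or "
        f"non-animal orthologs "
        f"({stats.formatted('invertebrate_only', 'total', 1)} of all genes)\n"
    )
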
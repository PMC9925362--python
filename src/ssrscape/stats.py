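"""Frequency, abundance and content statistics for mined SSRs.

Two senses of "frequency" appear in genome-wide SSR surveys and are kept
apart explicitly:

* ``frequency_of_total_pct`` — a unit-length category's share of all SSRs
  in the genome (the sense used in genome-distribution tables);
* ``frequency_within_unit_pct`` — a motif class's share of its unit-length
  category (the sense used in most-frequent-motif tables).

Abundance (also called diversity in the literature) is SSRs per Mb of the
sequence analysed; SSR content is summed SSR length as a percentage of
genome length.  Genome length denominators include N bases.  All statistics
are computed at full precision; :func:`round_half_up` provides the 2-decimal
half-up display rounding used in printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

from .mining import SSRRecord
from .motifs import MAX_UNIT_LENGTH

UNIT_LENGTH_NAMES = {
    1: "Mononucleotide",
    2: "Dinucleotide",
    3: "Trinucleotide",
    4: "Tetranucleotide",
    5: "Pentanucleotide",
    6: "Hexanucleotide",
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def unit_length_summary(
    ssrs: Iterable[SSRRecord], genome_length: int
) -> pd.DataFrame:
    """Per-unit-length counts, lengths, abundance and frequency from records."""
    counts = {k: 0 for k in range(1, MAX_UNIT_LENGTH + 1)}
    lengths = {k: 0 for k in range(1, MAX_UNIT_LENGTH + 1)}
    for ssr in ssrs:
        counts[ssr.unit_length] += 1
        lengths[ssr.unit_length] += ssr.length
    return unit_length_summary_from_counts(counts, lengths, genome_length)


def unit_length_summary_from_counts(
    counts: Mapping[int, int],
    lengths: Mapping[int, int],
    genome_length: int,
) -> pd.DataFrame:
    """Genome-distribution summary from per-unit-length counts and lengths.

    Rows are unit lengths 1-6 plus a ``total`` row; columns are ``count``,
    ``total_length_bp``, ``abundance_ssrs_per_mb`` and
    ``frequency_of_total_pct``.  The frame carries ``genome_length_bp`` and
    ``ssr_content_pct`` in ``DataFrame.attrs``.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    total_count = sum(counts.values())
    total_len = sum(lengths.values())
    mb = genome_length / 1e6
    rows = []
    for k in range(1, MAX_UNIT_LENGTH + 1):
        c = counts.get(k, 0)
        rows.append(
            {
                "unit_length": k,
                "count": c,
                "total_length_bp": lengths.get(k, 0),
                "abundance_ssrs_per_mb": c / mb,
                "frequency_of_total_pct": 100.0 * c / total_count if total_count else 0.0,
            }
        )
    rows.append(
        {
            "unit_length": "total",
            "count": total_count,
            "total_length_bp": total_len,
            "abundance_ssrs_per_mb": total_count / mb,
            "frequency_of_total_pct": 100.0 if total_count else 0.0,
        }
    )
    frame = pd.DataFrame(rows).set_index("unit_length")
    frame.attrs["genome_length_bp"] = int(genome_length)
    frame.attrs["ssr_content_pct"] = 100.0 * total_len / genome_length
    return frame


def motif_class_summary(ssrs: Iterable[SSRRecord]) -> pd.DataFrame:
    """Per-motif-class counts and within-unit-length frequencies.

    The class label is the canonical (lexicographically smallest) member;
    ``observed_label`` is the most frequent observed spelling at the mined
    loci, which is how published tables usually name classes.
    """
    class_counts: dict[tuple[int, str], int] = {}
    spellings: dict[tuple[int, str], dict[str, int]] = {}
    for ssr in ssrs:
        key = (ssr.unit_length, ssr.canonical)
        class_counts[key] = class_counts.get(key, 0) + 1
        sp = spellings.setdefault(key, {})
        sp[ssr.observed_unit] = sp.get(ssr.observed_unit, 0) + 1
    counts = {
        k: {canon: n for (kk, canon), n in class_counts.items() if kk == k}
        for k in sorted({kk for kk, _ in class_counts})
    }
    frame = motif_class_summary_from_counts(counts)
    frame["observed_label"] = [
        max(spellings[(k, c)].items(), key=lambda kv: (kv[1], kv[0]))[0]
        for k, c in zip(frame["unit_length"], frame["class_label"])
    ]
    return frame


def motif_class_summary_from_counts(
    counts: Mapping[int, Mapping[str, int]],
    unit_totals: Mapping[int, int] | None = None,
) -> pd.DataFrame:
    """Most-frequent-motif summary from per-class counts.

    ``counts`` maps unit length -> {class label: count}.  Labels are taken
    as given (so published representative spellings pass through); within
    each unit length classes are ranked by descending count, ties broken by
    label.  ``unit_totals`` overrides the percentage denominator per unit
    length — needed when ``counts`` holds only the top classes of a larger
    total, as published tables usually do.
    """
    rows = []
    for k in sorted(counts):
        unit_total = (
            unit_totals[k] if unit_totals is not None else sum(counts[k].values())
        )
        ranked = sorted(counts[k].items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (label, n) in enumerate(ranked, start=1):
            rows.append(
                {
                    "unit_length": k,
                    "class_label": label,
                    "count": n,
                    "frequency_within_unit_pct": 100.0 * n / unit_total if unit_total else 0.0,
                    "rank": rank,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["unit_length", "class_label", "count", "frequency_within_unit_pct", "rank"],
    )


def top_k_classes(class_summary: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top ``k`` motif classes across all unit lengths, with cumulative share.

    The cumulative percentage is of the genome-wide SSR total (the sum of
    all class counts in ``class_summary``).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = class_summary["count"].sum()
    ordered = class_summary.sort_values(
        ["count", "class_label"], ascending=[False, True]
    ).head(k)
    ordered = ordered.reset_index(drop=True)
    ordered["pct_of_all_ssrs"] = 100.0 * ordered["count"] / total
    ordered["cumulative_pct"] = ordered["pct_of_all_ssrs"].cumsum()
    return ordered


@dataclass
class GenomeSummary:
    """Named bundle of one genome's unit-length and motif-class summaries."""

    name: str
    unit_summary: pd.DataFrame
    class_summary: pd.DataFrame
    thresholds_definition: str = "1-12,2-6,3-5,4-5,5-4,6-4"


@dataclass
class ComparativeReport:
    """Side-by-side comparison of two genome summaries."""

    a: GenomeSummary
    b: GenomeSummary
    shared_classes: dict[int, list[str]]
    unique_to_a: dict[int, list[str]]
    unique_to_b: dict[int, list[str]]


def compare_genomes(
    a: GenomeSummary, b: GenomeSummary, top_n: int = 4
) -> ComparativeReport:
    """Shared and genome-unique top-``top_n`` motif classes per unit length."""
    if a.thresholds_definition != b.thresholds_definition:
        raise ValueError(
            "summaries were built with different mining thresholds: "
            f"{a.thresholds_definition} vs {b.thresholds_definition}"
        )

    def tops(summary: pd.DataFrame, k: int) -> set[str]:
        sub = summary[(summary["unit_length"] == k) & (summary["rank"] <= top_n)]
        return set(sub["class_label"])

    unit_lengths = sorted(
        set(a.class_summary["unit_length"]) | set(b.class_summary["unit_length"])
    )
    shared, only_a, only_b = {}, {}, {}
    for k in unit_lengths:
        ta, tb = tops(a.class_summary, k), tops(b.class_summary, k)
        shared[k] = sorted(ta & tb)
        only_a[k] = sorted(ta - tb)
        only_b[k] = sorted(tb - ta)
    return ComparativeReport(
        a=a, b=b, shared_classes=shared, unique_to_a=only_a, unique_to_b=only_b
    )
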
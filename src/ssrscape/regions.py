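"""Genomic region extraction from GFF3 and region-wise SSR statistics.

From a gene -> mRNA -> exon/CDS annotation this module derives six region
categories — gene, intergenic, exon, intron, CDS and UTR — as merged
interval sets, and counts SSRs per category.  Categories are deliberately
nested (gene contains exon and intron; exon contains CDS and UTR), so an
SSR is counted in *every* category it overlaps by at least 1 bp.  Densities
are SSRs per Mb of the category's merged total length.

Conventions:

* internal coordinates are 0-based half-open; GFF3 input (1-based
  inclusive) is converted on read;
* a base is exonic if it is exonic in any transcript, intronic if intronic
  in any transcript (unions across transcripts);
* UTR = exon minus CDS, per coding transcript, unioned;
* intergenic is the per-sequence complement of the merged gene spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd

from . import intervals as iv
from .mining import SSRRecord

CATEGORIES = ("gene", "intergenic", "exon", "intron", "CDS", "UTR")

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[iv.Interval, ...]  # sorted genomically, non-overlapping
    cds: tuple[iv.Interval, ...]

    @property
    def span(self) -> iv.Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[iv.Interval, ...]:
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(self.exons, self.exons[1:])
            if b_start > a_end
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seq_id: str
    strand: str
    span: iv.Interval
    transcripts: tuple[Transcript, ...]


def build_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Parse gene models (gene -> mRNA/transcript -> exon/CDS) from GFF3."""
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, level=1):
            if t.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = sorted((f.start - 1, f.end) for f in db.children(t, featuretype="exon"))
            cds = sorted((f.start - 1, f.end) for f in db.children(t, featuretype="CDS"))
            if not exons:
                continue
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping exons in transcript {t.id}")
            if iv.subtract(cds, exons):
                raise ValueError(f"CDS outside exons in transcript {t.id}")
            transcripts.append(Transcript(t.id, tuple(exons), tuple(cds)))
        genes.append(
            GeneModel(
                gene_id=g.id,
                seq_id=g.seqid,
                strand=g.strand,
                span=(g.start - 1, g.end),
                transcripts=tuple(transcripts),
            )
        )
    return genes


@dataclass
class RegionSet:
    """Merged intervals of one region category, per sequence."""

    category: str
    intervals: dict[str, list[iv.Interval]]

    @property
    def total_length(self) -> int:
        return sum(iv.total_length(ivs) for ivs in self.intervals.values())


def build_region_sets(
    annotation: str | Path | list[GeneModel],
    assembly_lengths: dict[str, int],
) -> dict[str, RegionSet]:
    """Derive the six region categories from annotation.

    ``annotation`` may be a GFF3 path or a pre-parsed list of
    :class:`GeneModel`.  ``assembly_lengths`` supplies per-sequence lengths
    for the intergenic complement; a gene on an unknown sequence raises.
    """
    genes = (
        annotation
        if isinstance(annotation, list)
        else build_gene_models(annotation)
    )
    per_seq: dict[str, dict[str, list[iv.Interval]]] = {
        cat: {sid: [] for sid in assembly_lengths} for cat in CATEGORIES
    }
    for g in genes:
        if g.seq_id not in assembly_lengths:
            raise ValueError(f"gene {g.gene_id} on unknown sequence {g.seq_id}")
        per_seq["gene"][g.seq_id].append(g.span)
        for t in g.transcripts:
            per_seq["exon"][g.seq_id].extend(t.exons)
            per_seq["intron"][g.seq_id].extend(t.introns)
            per_seq["CDS"][g.seq_id].extend(t.cds)
            if t.cds:
                per_seq["UTR"][g.seq_id].extend(iv.subtract(list(t.exons), list(t.cds)))

    out: dict[str, RegionSet] = {}
    for cat in CATEGORIES:
        if cat == "intergenic":
            merged = {
                sid: iv.complement(iv.merge(per_seq["gene"][sid]), length)
                for sid, length in assembly_lengths.items()
            }
        else:
            merged = {sid: iv.merge(ivs) for sid, ivs in per_seq[cat].items()}
        out[cat] = RegionSet(category=cat, intervals=merged)
    return out


def categories_for(ssr: SSRRecord, regions: dict[str, RegionSet]) -> set[str]:
    """All categories the SSR overlaps by >= 1 bp."""
    out = set()
    for cat, rs in regions.items():
        if ssr.seq_id not in rs.intervals:
            raise ValueError(f"SSR sequence {ssr.seq_id} absent from region sets")
        if iv.overlaps_any(rs.intervals[ssr.seq_id], ssr.start, ssr.end):
            out.add(cat)
    return out


def assign_ssrs(
    ssrs: list[SSRRecord],
    regions: dict[str, RegionSet],
) -> pd.DataFrame:
    """Region-wise SSR counts and densities.

    Returns a DataFrame indexed by category with columns ``count``,
    ``total_length_bp`` and ``density_ssrs_per_mb``.
    """
    counts = {cat: 0 for cat in regions}
    for ssr in ssrs:
        for cat in categories_for(ssr, regions):
            counts[cat] += 1
    rows = []
    for cat, rs in regions.items():
        length = rs.total_length
        density = counts[cat] / (length / 1e6) if length > 0 else 0.0
        rows.append(
            {
                "category": cat,
                "count": counts[cat],
                "total_length_bp": length,
                "density_ssrs_per_mb": density,
            }
        )
    return pd.DataFrame(rows).set_index("category")
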
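"""Gene-element partition and relative-position profiling of SSRs.

Genes with at least seven exons are split, 5'->3', into 13 elements:

    upstream500, exon1, intron1, exon2, intron2, middle_left_exon,
    middle_intron, middle_right_exon, last2_intron, last2_exon,
    last_intron, last_exon, downstream500

First/second and last/second-to-last exons and introns are taken from the
gene's 5' and 3' ends; the remaining "middle" exons are split into a left
and a right half (odd exon to the left), and all remaining introns are
pooled as ``middle_intron``.  Flanks are the 500 bp immediately upstream
and downstream of the gene span, clipped at sequence ends.

Within an element, an SSR's relative position is

    value = (5'-offset of the SSR within the element) / (element length - SSR length)

binned into tenths P0.1 .. P1.0 (value 0 goes to P0.1; an SSR exactly the
element's length gets the mid value 0.5).  SSRs that straddle an element
boundary are counted once, in the element holding the greater share (ties
to the 5' element), without a bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import intervals as iv
from .mining import SSRRecord
from .regions import GeneModel, Transcript

ELEMENT_LABELS = (
    "upstream500",
    "exon1",
    "intron1",
    "exon2",
    "intron2",
    "middle_left_exon",
    "middle_intron",
    "middle_right_exon",
    "last2_intron",
    "last2_exon",
    "last_intron",
    "last_exon",
    "downstream500",
)
_ELEMENT_ORDER = {label: i for i, label in enumerate(ELEMENT_LABELS)}

EXON_LABELS = ("exon1", "exon2", "middle_left_exon", "middle_right_exon", "last2_exon", "last_exon")
INTRON_LABELS = ("intron1", "intron2", "middle_intron", "last2_intron", "last_intron")

BINS = tuple(f"P{i / 10:.1f}" for i in range(1, 11))

DEFAULT_FLANK = 500
DEFAULT_MIN_EXONS = 7


def representative_transcript(gene: GeneModel) -> Transcript:
    """The transcript with the most exons (ties broken by id)."""
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return max(gene.transcripts, key=lambda t: (len(t.exons), t.transcript_id))


def select_multiexon_genes(
    genes: Iterable[GeneModel], min_exons: int = DEFAULT_MIN_EXONS
) -> list[GeneModel]:
    """Genes whose representative transcript has >= ``min_exons`` exons.

    The default of 7 exons forces >= 6 introns, so every one of the 13
    elements is populated.
    """
    return [
        g
        for g in genes
        if g.transcripts and len(representative_transcript(g).exons) >= min_exons
    ]


@dataclass
class ElementPartition:
    """The 13 labelled element intervals of one gene (genomic coordinates)."""

    gene_id: str
    seq_id: str
    strand: str
    elements: dict[str, list[iv.Interval]]

    @property
    def extent(self) -> iv.Interval:
        lo = min(s for ivs in self.elements.values() for s, _ in ivs)
        hi = max(e for ivs in self.elements.values() for _, e in ivs)
        return (lo, hi)

    def element_length(self, label: str) -> int:
        return sum(e - s for s, e in self.elements[label])


def partition_gene_elements(
    gene: GeneModel,
    seq_length: int,
    flank: int = DEFAULT_FLANK,
    min_exons: int = DEFAULT_MIN_EXONS,
) -> ElementPartition:
    """Split a multi-exon gene into the 13 labelled elements."""
    t = representative_transcript(gene)
    n = len(t.exons)
    if n < min_exons:
        raise ValueError(
            f"gene {gene.gene_id} has {n} exons; needs >= {min_exons} for the partition"
        )
    exons = list(t.exons)  # genomic order
    introns = list(t.introns)
    if gene.strand == "-":
        exons_5p = exons[::-1]
        introns_5p = introns[::-1]
    else:
        exons_5p = exons
        introns_5p = introns

    middle = exons_5p[2:-2]
    left = middle[: math.ceil(len(middle) / 2)]
    right = middle[len(left):]

    gs, ge = gene.span
    if gene.strand == "-":
        upstream = (ge, min(seq_length, ge + flank))
        downstream = (max(0, gs - flank), gs)
    else:
        upstream = (max(0, gs - flank), gs)
        downstream = (ge, min(seq_length, ge + flank))

    elements: dict[str, list[iv.Interval]] = {
        "upstream500": [upstream] if upstream[1] > upstream[0] else [],
        "exon1": [exons_5p[0]],
        "intron1": [introns_5p[0]],
        "exon2": [exons_5p[1]],
        "intron2": [introns_5p[1]],
        "middle_left_exon": list(left),
        "middle_intron": list(introns_5p[2:-2]),
        "middle_right_exon": list(right),
        "last2_intron": [introns_5p[-2]],
        "last2_exon": [exons_5p[-2]],
        "last_intron": [introns_5p[-1]],
        "last_exon": [exons_5p[-1]],
        "downstream500": [downstream] if downstream[1] > downstream[0] else [],
    }
    return ElementPartition(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        strand=gene.strand,
        elements={label: sorted(ivs) for label, ivs in elements.items()},
    )


@dataclass(frozen=True)
class RelativePosition:
    """Relative position of an SSR within an element interval."""

    value: float
    bin: str


def relative_position(
    ssr: SSRRecord, element_interval: iv.Interval, strand: str
) -> RelativePosition:
    """Relative position of an SSR fully contained in ``element_interval``.

    The offset is measured from the element's 5' end to the SSR's
    5'-proximal end and divided by (element length - SSR length); a
    degenerate denominator (SSR fills the element) yields 0.5, the only
    strand-symmetric choice.  The value is clamped to [0, 1].
    """
    es, ee = element_interval
    if not (es <= ssr.start and ssr.end <= ee):
        raise ValueError(
            f"SSR [{ssr.start},{ssr.end}) not contained in element [{es},{ee})"
        )
    denom = (ee - es) - ssr.length
    if denom == 0:
        value = 0.5
    else:
        offset = ssr.start - es if strand != "-" else ee - ssr.end
        value = min(1.0, max(0.0, offset / denom))
    return RelativePosition(value=value, bin=position_bin(value))


def position_bin(value: float) -> str:
    """Tenth-bin label for a relative position in [0, 1]; 0 maps to P0.1."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"relative position out of [0,1]: {value}")
    b = max(1, math.ceil(round(value * 10, 9)))
    return f"P{b / 10:.1f}"


@dataclass(frozen=True)
class ElementAssignment:
    """One SSR placed in one gene element (bin absent for boundary-spanners)."""

    ssr: SSRRecord
    gene_id: str
    label: str
    position: RelativePosition | None


def assign_elements(
    ssrs: Sequence[SSRRecord],
    partitions: Sequence[ElementPartition],
) -> list[ElementAssignment]:
    """Place SSRs into gene elements, one element per (SSR, gene).

    An SSR fully contained in an element interval gets a relative-position
    bin; one straddling element boundaries is counted in the element with
    the greater overlap (ties to the more-5' element) without a bin.  An
    SSR overlapping the partitions of several genes is counted in each.
    """
    by_seq: dict[str, list[ElementPartition]] = {}
    for p in partitions:
        by_seq.setdefault(p.seq_id, []).append(p)

    out: list[ElementAssignment] = []
    for ssr in ssrs:
        for part in by_seq.get(ssr.seq_id, []):
            lo, hi = part.extent
            if ssr.end <= lo or ssr.start >= hi:
                continue
            best: tuple[int, int, str, iv.Interval | None] | None = None
            contained: tuple[str, iv.Interval] | None = None
            for label, ivs in part.elements.items():
                for interval in ivs:
                    ov = max(0, min(interval[1], ssr.end) - max(interval[0], ssr.start))
                    if ov == 0:
                        continue
                    if interval[0] <= ssr.start and ssr.end <= interval[1]:
                        contained = (label, interval)
                    key = (-ov, _ELEMENT_ORDER[label], label, interval)
                    if best is None or key[:2] < best[:2]:
                        best = key
            if contained is not None:
                label, interval = contained
                out.append(
                    ElementAssignment(
                        ssr, part.gene_id, label,
                        relative_position(ssr, interval, part.strand),
                    )
                )
            elif best is not None:
                out.append(ElementAssignment(ssr, part.gene_id, best[2], None))
    return out


@dataclass
class ElementProfile:
    """Per-element SSR counts, lengths, abundance and relative-position bins."""

    counts: dict[str, int]
    bin_counts: dict[tuple[str, str], int]
    lengths: dict[str, int]
    n_genes: int

    def abundance(self, label: str) -> float:
        length = self.lengths[label]
        return self.counts[label] / (length / 1e6) if length else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element_label": label,
                "n_genes": self.n_genes,
                "total_length_bp": self.lengths[label],
                "ssr_count": self.counts[label],
                "abundance_ssrs_per_mb": self.abundance(label),
            }
            for label in ELEMENT_LABELS
        ]
        return pd.DataFrame(rows).set_index("element_label")

    def bins_frame(self) -> pd.DataFrame:
        rows = [
            {"element_label": label, "bin": b, "count": self.bin_counts.get((label, b), 0)}
            for label in ELEMENT_LABELS
            for b in BINS
        ]
        return pd.DataFrame(rows)


def element_profile(
    ssrs: Sequence[SSRRecord],
    partitions: Sequence[ElementPartition],
) -> ElementProfile:
    """Aggregate :func:`assign_elements` into the Fig-2-style profile."""
    counts = {label: 0 for label in ELEMENT_LABELS}
    bin_counts: dict[tuple[str, str], int] = {}
    lengths = {label: 0 for label in ELEMENT_LABELS}
    for part in partitions:
        for label in ELEMENT_LABELS:
            lengths[label] += part.element_length(label)
    for a in assign_elements(ssrs, partitions):
        counts[a.label] += 1
        if a.position is not None:
            key = (a.label, a.position.bin)
            bin_counts[key] = bin_counts.get(key, 0) + 1
    return ElementProfile(
        counts=counts,
        bin_counts=bin_counts,
        lengths=lengths,
        n_genes=len(partitions),
    )


def plot_profile(profile: ElementProfile, path: str) -> None:
    """Bar plot of per-element SSR abundance (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = profile.to_frame()
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.bar(frame.index, frame["abundance_ssrs_per_mb"], color="#4878a8")
    ax.set_ylabel("SSR abundance (SSRs/Mb)")
    ax.set_xlabel("gene element (5' -> 3')")
    plt.setp(ax.get_xticklabels(), rotation=60, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
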
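"""Perfect microsatellite detection and compound-SSR merging.

The miner reports every maximal perfect tandem run whose primitive unit is
1-6 bp long and whose whole-unit repeat count meets a per-unit-length
minimum.  Defaults follow the widely used MISA-style definition
``1-12, 2-6, 3-5, 4-5, 5-4, 6-4`` (e.g. a mononucleotide run must repeat at
least 12 times).  Conventions:

* a run is reported once, under its primitive unit — 12 consecutive A's are
  one mononucleotide SSR, never also an (AA)x6 dinucleotide;
* partial trailing units are dropped: the record spans whole units only and
  is anchored at the left end of the character-level run;
* ``N`` and any other non-ACGT character is a hard break;
* when candidate runs of different unit lengths overlap (rare), the earliest
  start wins, ties going to the shorter unit, so that each position belongs
  to at most one reported SSR.

Two SSRs on the same sequence separated by strictly fewer than 100 bp are
chained (transitively) into a *compound* SSR; compound members keep their
individual records for all count statistics.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

from .motifs import MAX_UNIT_LENGTH, canonical_label, is_primitive

DEFAULT_MIN_REPEATS: Mapping[int, int] = {1: 12, 2: 6, 3: 5, 4: 5, 5: 4, 6: 4}
DEFAULT_COMPOUND_GAP = 100


@dataclass(frozen=True)
class MiningThresholds:
    """Per-unit-length minimum repeat counts plus the compound-merge gap.

    ``min_repeats`` maps unit length (1-6) to the minimum number of whole
    units a run must contain; ``compound_max_gap`` is the strict upper bound
    on the distance between two SSRs merged into a compound.
    """

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_max_gap: int = DEFAULT_COMPOUND_GAP

    def __post_init__(self) -> None:
        for k, m in self.min_repeats.items():
            if not 1 <= k <= MAX_UNIT_LENGTH:
                raise ValueError(f"unit length out of range: {k}")
            if m < 2:
                raise ValueError(f"minimum repeat count must be >= 2, got {m} for k={k}")
        if self.compound_max_gap < 0:
            raise ValueError("compound_max_gap must be non-negative")

    @classmethod
    def from_definition(cls, definition: str, compound_max_gap: int = DEFAULT_COMPOUND_GAP):
        """Parse a MISA-style definition string such as ``"1-12,2-6,3-5,4-5,5-4,6-4"``."""
        pairs = {}
        for item in definition.split(","):
            k, _, m = item.strip().partition("-")
            pairs[int(k)] = int(m)
        return cls(min_repeats=pairs, compound_max_gap=compound_max_gap)

    def to_definition(self) -> str:
        return ",".join(f"{k}-{m}" for k, m in sorted(self.min_repeats.items()))


@dataclass(frozen=True)
class SSRRecord:
    """One detected perfect microsatellite.

    Coordinates are 0-based half-open on the forward strand.
    ``observed_unit`` is the unit as read at the locus; ``canonical`` is its
    motif-class label (smallest member under rotation/reverse-complement).
    """

    seq_id: str
    start: int
    end: int
    observed_unit: str
    canonical: str
    unit_length: int
    repeat_count: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_length * self.repeat_count:
            raise ValueError(
                f"inconsistent SSR span: [{self.start},{self.end}) != "
                f"{self.unit_length} x {self.repeat_count}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_misa_motif(self) -> str:
        return f"({self.observed_unit}){self.repeat_count}"


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more SSRs whose successive gaps are each below the merge cutoff."""

    seq_id: str
    members: tuple[SSRRecord, ...]
    gaps: tuple[int, ...]

    @property
    def span_start(self) -> int:
        return self.members[0].start

    @property
    def span_end(self) -> int:
        return self.members[-1].end


_ACGT_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


def find_perfect_ssrs(
    sequence: str,
    thresholds: MiningThresholds | None = None,
    seq_id: str = "seq",
) -> list[SSRRecord]:
    """All maximal perfect SSRs in ``sequence`` meeting ``thresholds``.

    Case-insensitive; characters outside A/C/G/T terminate runs rather than
    raising.  Records are returned sorted by start, pairwise non-overlapping.
    """
    if thresholds is None:
        thresholds = MiningThresholds()
    seq = sequence.upper()
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, _ACGT_CODES)

    candidates: list[tuple[int, int, int, str]] = []  # (start, k, count, unit)
    for k, min_rep in sorted(thresholds.min_repeats.items()):
        if n < k * min_rep:
            continue
        eq = (arr[:-k] == arr[k:]) & valid[:-k] & valid[k:]
        edges = np.flatnonzero(np.diff(np.r_[np.int8(0), eq.view(np.int8), np.int8(0)]))
        for a, b in zip(edges[0::2], edges[1::2]):
            # equality holds for positions [a, b): character run is [a, b + k)
            count = int(b - a + k) // k
            if count < min_rep:
                continue
            unit = seq[a : a + k]
            if not is_primitive(unit):
                continue
            candidates.append((int(a), k, count, unit))

    candidates.sort(key=lambda c: (c[0], c[1]))
    records: list[SSRRecord] = []
    frontier = 0
    for a, k, count, unit in candidates:
        if records and a < frontier:
            continue
        records.append(
            SSRRecord(
                seq_id=seq_id,
                start=a,
                end=a + k * count,
                observed_unit=unit,
                canonical=canonical_label(unit),
                unit_length=k,
                repeat_count=count,
            )
        )
        frontier = a + k * count
    return records


def merge_compound(
    ssrs: Iterable[SSRRecord],
    max_gap: int = DEFAULT_COMPOUND_GAP,
) -> tuple[list[CompoundSSR], list[SSRRecord]]:
    """Chain SSRs with inter-record gaps strictly below ``max_gap``.

    Input must be sorted by start, on a single sequence, non-overlapping.
    Chaining is transitive: gaps of 50 and 50 bp yield one 3-member
    compound.  Returns ``(compounds, standalone)``; every input record
    appears in exactly one of the two.
    """
    ssrs = list(ssrs)
    for prev, nxt in zip(ssrs, ssrs[1:]):
        if prev.seq_id != nxt.seq_id:
            raise ValueError("merge_compound expects records from a single sequence")
        if nxt.start < prev.end:
            raise ValueError("merge_compound expects sorted, non-overlapping records")

    compounds: list[CompoundSSR] = []
    standalone: list[SSRRecord] = []
    chain: list[SSRRecord] = []

    def _flush() -> None:
        if len(chain) >= 2:
            gaps = tuple(b.start - a.end for a, b in zip(chain, chain[1:]))
            compounds.append(CompoundSSR(chain[0].seq_id, tuple(chain), gaps))
        elif chain:
            standalone.append(chain[0])
        chain.clear()

    for rec in ssrs:
        if chain and rec.start - chain[-1].end < max_gap:
            chain.append(rec)
        else:
            _flush()
            chain.append(rec)
    _flush()
    return compounds, standalone


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(seq_id, sequence)`` from a (possibly gzipped) FASTA file."""
    with _open_maybe_gzip(Path(path)) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq)


@dataclass
class GenomeMiningResult:
    """SSRs mined from a whole assembly plus the length bookkeeping.

    ``assembly_length`` includes N bases and is the denominator used for
    SSRs/Mb abundance.
    """

    records: list[SSRRecord]
    seq_lengths: dict[str, int]
    thresholds: MiningThresholds

    @property
    def assembly_length(self) -> int:
        return sum(self.seq_lengths.values())

    def per_sequence(self) -> dict[str, list[SSRRecord]]:
        out: dict[str, list[SSRRecord]] = {sid: [] for sid in self.seq_lengths}
        for rec in self.records:
            out[rec.seq_id].append(rec)
        return out

    def compounds(self) -> tuple[list[CompoundSSR], list[SSRRecord]]:
        """Compound/standalone split over the whole assembly."""
        compounds: list[CompoundSSR] = []
        standalone: list[SSRRecord] = []
        for recs in self.per_sequence().values():
            c, s = merge_compound(recs, self.thresholds.compound_max_gap)
            compounds.extend(c)
            standalone.extend(s)
        return compounds, standalone


def mine_genome(
    fasta_path: str | Path,
    thresholds: MiningThresholds | None = None,
) -> GenomeMiningResult:
    """Run :func:`find_perfect_ssrs` over every sequence of a FASTA assembly."""
    if thresholds is None:
        thresholds = MiningThresholds()
    records: list[SSRRecord] = []
    seq_lengths: dict[str, int] = {}
    for seq_id, seq in iter_fasta(fasta_path):
        if seq_id in seq_lengths:
            raise ValueError(f"duplicate sequence id in FASTA: {seq_id}")
        seq_lengths[seq_id] = len(seq)
        records.extend(find_perfect_ssrs(seq, thresholds, seq_id=seq_id))
    if not seq_lengths:
        raise ValueError(f"no sequences found in {fasta_path}")
    return GenomeMiningResult(records=records, seq_lengths=seq_lengths, thresholds=thresholds)
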
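"""Seeded synthetic assemblies with planted SSRs and exact ground truth.

The generator emits a multi-sequence FASTA, a matching gene -> mRNA ->
exon/CDS GFF3 and a truth table, built so that every other module is
testable without real assemblies:

* the background sequence is uniform-random ACGT *sterilized* of
  threshold-passing SSRs (detected runs are broken by substitution and
  re-checked to a fixed point), so the only SSRs present are the planted
  ones;
* each planted repeat is written with flanking bases chosen to break
  unit extension on both sides, making it maximal — mined coordinates must
  equal planted coordinates exactly, not just overlap;
* planted SSRs are kept >= 120 bp apart (beyond the 100 bp compound
  cutoff) unless a chain with explicit gaps is requested;
* gene models carry configurable exon/intron lengths, strands, UTRs and
  N-runs in intergenic space.

The truth table records, for every planted SSR, its coordinates, unit,
canonical class, repeat count, overlapped region categories, gene element
label and relative-position bin — all derived from the generator's own
layout bookkeeping, not by running the annotation modules.

Everything is a pure function of the configuration (which carries the
seed): identical configs give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import intervals as iv
from .mining import MiningThresholds, find_perfect_ssrs
from .motifs import canonical_label, normalize_unit
from .positions import ELEMENT_LABELS, position_bin

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MIN_SEPARATION = 120  # bp between planted chains; > the 100 bp compound cutoff


class SimulationError(ValueError):
    """Raised for infeasible planting specifications."""


@dataclass(frozen=True)
class GeneTemplate:
    """Explicit geometry of one gene: exon/intron lengths 5'->3' and UTRs."""

    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    strand: str = "+"
    utr5: int = 60  # bp of the 5'-most exon before the CDS
    utr3: int = 60  # bp of the 3'-most exon after the CDS

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise SimulationError("need exactly one fewer intron than exons")
        if self.strand not in "+-":
            raise SimulationError(f"bad strand {self.strand!r}")
        first = self.exon_lengths[0] if self.strand == "+" else self.exon_lengths[-1]
        last = self.exon_lengths[-1] if self.strand == "+" else self.exon_lengths[0]
        if not 0 <= self.utr5 < first or not 0 <= self.utr3 < last:
            raise SimulationError("UTR longer than its terminal exon")

    @property
    def span_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass(frozen=True)
class SequencePlan:
    """One synthetic sequence: genes separated by intergenic gaps.

    ``gaps`` has ``len(genes) + 1`` entries: leading gap, inter-gene gaps,
    trailing gap.  ``n_run`` optionally places a run of N of that length in
    the middle of the leading gap (assemblies have N runs; they are hard
    breaks for the miner).
    """

    seq_id: str
    genes: tuple[GeneTemplate, ...]
    gaps: tuple[int, ...]
    n_run: int = 0

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.genes) + 1:
            raise SimulationError("need len(genes) + 1 intergenic gaps")

    @property
    def length(self) -> int:
        return sum(self.gaps) + sum(g.span_length for g in self.genes)


@dataclass(frozen=True)
class PlantRequest:
    """One SSR (or an explicit chain of SSRs) to plant.

    ``target`` is a region category (``intergenic``, ``intron``, ``CDS``,
    ``UTR``) or a gene-element label (``exon1`` ... ``downstream500``).
    ``rel_position`` pins the relative position within the (single-interval)
    target element.  ``chain``/``chain_gaps`` plant several SSRs as one
    block with the given inter-record gaps (>= 2 bp), e.g. to build
    compound SSRs.
    """

    unit: str = ""
    repeat_count: int = 0
    target: str = "intergenic"
    rel_position: float | None = None
    chain: tuple[tuple[str, int], ...] = ()
    chain_gaps: tuple[int, ...] = ()

    def members(self) -> tuple[tuple[str, int], ...]:
        if self.chain:
            if len(self.chain_gaps) != len(self.chain) - 1:
                raise SimulationError("need len(chain) - 1 chain gaps")
            if any(g < 2 for g in self.chain_gaps):
                raise SimulationError("chain gaps must be >= 2 bp")
            return tuple((normalize_unit(u), c) for u, c in self.chain)
        return ((normalize_unit(self.unit), self.repeat_count),)

    @property
    def block_length(self) -> int:
        return sum(len(u) * c for u, c in self.members()) + sum(self.chain_gaps)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    sequences: tuple[SequencePlan, ...]
    plants: tuple[PlantRequest, ...]
    thresholds: MiningThresholds = field(default_factory=MiningThresholds)
    flank: int = 500
    min_exons: int = 7


# ---------------------------------------------------------------------------
# layout bookkeeping


@dataclass
class _GeneLayout:
    gene_id: str
    seq_id: str
    strand: str
    span: iv.Interval
    exons: list[iv.Interval]      # genomic order
    introns: list[iv.Interval]
    cds: list[iv.Interval]
    utr: list[iv.Interval]
    elements: dict[str, list[iv.Interval]] | None  # None if too few exons


def _layout_gene(
    template: GeneTemplate, start: int, gene_id: str, seq_id: str,
    seq_length: int, flank: int, min_exons: int,
) -> _GeneLayout:
    exons: list[iv.Interval] = []
    cursor = start
    for i, elen in enumerate(template.exon_lengths):
        exons.append((cursor, cursor + elen))
        cursor += elen
        if i < len(template.intron_lengths):
            cursor += template.intron_lengths[i]
    end = cursor
    introns = [
        (a_end, b_start) for (_, a_end), (b_start, _) in zip(exons, exons[1:])
    ]
    if template.strand == "+":
        cds_lo, cds_hi = start + template.utr5, end - template.utr3
    else:
        cds_lo, cds_hi = start + template.utr3, end - template.utr5
    cds = [
        (max(s, cds_lo), min(e, cds_hi))
        for s, e in exons
        if min(e, cds_hi) > max(s, cds_lo)
    ]
    utr = iv.subtract(exons, cds)

    elements: dict[str, list[iv.Interval]] | None = None
    if len(exons) >= min_exons:
        e5 = exons[::-1] if template.strand == "-" else exons
        i5 = introns[::-1] if template.strand == "-" else introns
        middle = e5[2:-2]
        left = middle[: math.ceil(len(middle) / 2)]
        right = middle[len(left):]
        if template.strand == "-":
            up = (end, min(seq_length, end + flank))
            down = (max(0, start - flank), start)
        else:
            up = (max(0, start - flank), start)
            down = (end, min(seq_length, end + flank))
        elements = {
            "upstream500": [up] if up[1] > up[0] else [],
            "exon1": [e5[0]],
            "intron1": [i5[0]],
            "exon2": [e5[1]],
            "intron2": [i5[1]],
            "middle_left_exon": sorted(left),
            "middle_intron": sorted(i5[2:-2]),
            "middle_right_exon": sorted(right),
            "last2_intron": [i5[-2]],
            "last2_exon": [e5[-2]],
            "last_intron": [i5[-1]],
            "last_exon": [e5[-1]],
            "downstream500": [down] if down[1] > down[0] else [],
        }
    return _GeneLayout(
        gene_id=gene_id, seq_id=seq_id, strand=template.strand,
        span=(start, end), exons=exons, introns=introns,
        cds=cds, utr=utr, elements=elements,
    )


@dataclass
class _SeqLayout:
    seq_id: str
    length: int
    genes: list[_GeneLayout]
    intergenic: list[iv.Interval]
    n_zone: iv.Interval | None


def _layout_sequence(
    plan: SequencePlan, gene_counter: int, flank: int, min_exons: int
) -> _SeqLayout:
    seq_length = plan.length
    genes: list[_GeneLayout] = []
    cursor = 0
    for i, (gap, template) in enumerate(zip(plan.gaps, plan.genes)):
        cursor += gap
        genes.append(
            _layout_gene(
                template, cursor, f"gene{gene_counter + i:04d}", plan.seq_id,
                seq_length, flank, min_exons,
            )
        )
        cursor += template.span_length
    intergenic = iv.complement([g.span for g in genes], seq_length)
    n_zone = None
    if plan.n_run > 0:
        lead = plan.gaps[0]
        if plan.n_run + 20 > lead:
            raise SimulationError("leading gap too small for the requested N run")
        mid = lead // 2
        n_zone = (mid - plan.n_run // 2, mid - plan.n_run // 2 + plan.n_run)
    return _SeqLayout(plan.seq_id, seq_length, genes, intergenic, n_zone)


# ---------------------------------------------------------------------------
# background


def generate_background(
    length: int,
    rng: int | np.random.Generator,
    thresholds: MiningThresholds | None = None,
) -> str:
    """Uniform-random ACGT string with no threshold-passing SSR.

    Detected runs are broken by a single mid-run substitution and the
    string re-checked, iterating to a fixed point (a handful of rounds
    even at megabase lengths).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if thresholds is None:
        thresholds = MiningThresholds()
    if length == 0:
        return ""
    arr = rng.choice(_BASES, size=length)
    for _ in range(100):
        seq = arr.tobytes().decode("ascii")
        records = find_perfect_ssrs(seq, thresholds)
        if not records:
            return seq
        for rec in records:
            pos = (rec.start + rec.end) // 2
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = rng.choice(choices)
    raise SimulationError("background sterilization did not converge")


# ---------------------------------------------------------------------------
# planting


def _categories_of(layout: _SeqLayout, start: int, end: int) -> set[str]:
    cats: set[str] = set()
    for g in layout.genes:
        if iv.overlaps_any([g.span], start, end):
            cats.add("gene")
        if iv.overlaps_any(g.exons, start, end):
            cats.add("exon")
        if iv.overlaps_any(g.introns, start, end):
            cats.add("intron")
        if iv.overlaps_any(g.cds, start, end):
            cats.add("CDS")
        if iv.overlaps_any(g.utr, start, end):
            cats.add("UTR")
    if iv.overlaps_any(layout.intergenic, start, end):
        cats.add("intergenic")
    return cats


def _element_of(
    layout: _SeqLayout, start: int, end: int
) -> tuple[str, float | None] | tuple[None, None]:
    """(element label, relative-position value) per the profiler's rules."""
    for g in layout.genes:
        if g.elements is None:
            continue
        best: tuple[int, int, str] | None = None
        contained: tuple[str, iv.Interval] | None = None
        for order, label in enumerate(ELEMENT_LABELS):
            for interval in g.elements[label]:
                ov = max(0, min(interval[1], end) - max(interval[0], start))
                if ov == 0:
                    continue
                if interval[0] <= start and end <= interval[1]:
                    contained = (label, interval)
                if best is None or (-ov, order) < best[:2]:
                    best = (-ov, order, label)
        if contained is not None:
            label, (es, ee) = contained
            denom = (ee - es) - (end - start)
            if denom == 0:
                return label, 0.5
            offset = start - es if g.strand != "-" else ee - end
            return label, min(1.0, max(0.0, offset / denom))
        if best is not None:
            return best[2], None
    return None, None


def _candidate_intervals(layout: _SeqLayout, target: str, flank: int) -> list[iv.Interval]:
    if target == "intergenic":
        # keep clear of profiled-gene flanks so the element label stays empty
        shrunk = []
        flanked = iv.merge(
            [
                (max(0, g.span[0] - flank - 10), min(layout.length, g.span[1] + flank + 10))
                for g in layout.genes
            ]
        )
        for s, e in iv.subtract(layout.intergenic, flanked):
            shrunk.append((s, e))
        return shrunk
    if target == "intron":
        return [i for g in layout.genes for i in g.introns]
    if target == "CDS":
        return [i for g in layout.genes for i in g.cds]
    if target == "UTR":
        return [i for g in layout.genes for i in g.utr]
    if target == "exon":
        return [i for g in layout.genes for i in g.exons]
    if target in ELEMENT_LABELS:
        return [
            i
            for g in layout.genes
            if g.elements is not None
            for i in g.elements[target]
        ]
    raise SimulationError(f"unknown planting target {target!r}")


@dataclass
class SimulatedGenome:
    """Sequences, annotation and truth table of one simulation run."""

    config: SimulationConfig
    sequences: dict[str, str]
    layouts: list[_SeqLayout]
    truth: pd.DataFrame

    @property
    def assembly_lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.sequences.items()}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for layout in self.layouts:
                fh.write(f"##sequence-region {layout.seq_id} 1 {layout.length}\n")
            rna_n = 0
            for layout in self.layouts:
                for g in layout.genes:
                    rna_n += 1
                    rna_id = f"rna{rna_n:04d}"
                    s, e = g.span
                    common = f"{layout.seq_id}\tssrscape_sim"
                    fh.write(
                        f"{common}\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                    )
                    fh.write(
                        f"{common}\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={rna_id};Parent={g.gene_id}\n"
                    )
                    for i, (xs, xe) in enumerate(g.exons, start=1):
                        fh.write(
                            f"{common}\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                            f"ID={rna_id}.exon{i};Parent={rna_id}\n"
                        )
                    cds_5p = g.cds[::-1] if g.strand == "-" else g.cds
                    phase = 0
                    phases = {}
                    for cs, ce in cds_5p:
                        phases[(cs, ce)] = phase
                        phase = (3 - ((ce - cs) - phase) % 3) % 3
                    for i, (cs, ce) in enumerate(g.cds, start=1):
                        fh.write(
                            f"{common}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t"
                            f"{phases[(cs, ce)]}\tID={rna_id}.cds;Parent={rna_id}\n"
                        )

    def write_truth_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate(config: SimulationConfig) -> SimulatedGenome:
    """Build the synthetic assembly, annotation and truth table."""
    rng = np.random.default_rng(config.seed)
    layouts: list[_SeqLayout] = []
    gene_counter = 1
    for plan in config.sequences:
        layouts.append(_layout_sequence(plan, gene_counter, config.flank, config.min_exons))
        gene_counter += len(plan.genes)

    arrays: dict[str, np.ndarray] = {}
    blocked: dict[str, list[iv.Interval]] = {}
    for layout in layouts:
        bg = generate_background(layout.length, rng, config.thresholds)
        arr = np.frombuffer(bg.encode("ascii"), dtype=np.uint8).copy()
        zones: list[iv.Interval] = [(-10, 2), (layout.length - 2, layout.length + 10)]
        if layout.n_zone is not None:
            s, e = layout.n_zone
            arr[s:e] = ord("N")
            zones.append((s - MIN_SEPARATION, e + MIN_SEPARATION))
        arrays[layout.seq_id] = arr
        blocked[layout.seq_id] = iv.merge(zones)

    truth_rows: list[dict] = []
    expected: dict[str, set[tuple[int, int, str]]] = {l.seq_id: set() for l in layouts}
    layout_by_id = {l.seq_id: l for l in layouts}

    for req_idx, req in enumerate(config.plants):
        members = req.members()
        block_len = req.block_length
        placed = False
        # deterministic, seeded scan over candidate host intervals
        candidates = [
            (layout, interval)
            for layout in layouts
            for interval in _candidate_intervals(layout, req.target, config.flank)
            if interval[1] - interval[0] >= block_len + 4
        ]
        if not candidates:
            raise SimulationError(
                f"no interval of type {req.target!r} can host request #{req_idx} "
                f"({block_len} bp)"
            )
        order = rng.permutation(len(candidates))
        for ci in order:
            layout, (cs, ce) = candidates[ci]
            if req.rel_position is not None:
                if len(members) != 1:
                    raise SimulationError("rel_position only supported for single SSRs")
                denom = (ce - cs) - block_len
                offset = round(req.rel_position * denom)
                strand = "+"
                for g in layout.genes:
                    if g.elements and any(
                        (cs, ce) in ivs for ivs in g.elements.values()
                    ):
                        strand = g.strand
                        break
                start = cs + offset if strand != "-" else ce - offset - block_len
                starts = [start]
            else:
                lo, hi = cs + 2, ce - 2 - block_len
                if hi < lo:
                    continue
                starts = list(rng.integers(lo, hi + 1, size=8))
            for start in starts:
                start = int(start)
                # blocked spans are already padded by the separation margin
                if iv.overlaps_any(blocked[layout.seq_id], start, start + block_len):
                    continue
                span = (start - MIN_SEPARATION, start + block_len + MIN_SEPARATION)
                _write_chain(arrays[layout.seq_id], start, members, req.chain_gaps, rng)
                blocked[layout.seq_id] = iv.merge(
                    blocked[layout.seq_id] + [span]
                )
                cursor = start
                for mi, (unit, count) in enumerate(members):
                    s, e = cursor, cursor + len(unit) * count
                    expected[layout.seq_id].add((s, e, unit))
                    label, value = _element_of(layout, s, e)
                    truth_rows.append(
                        {
                            "seq_id": layout.seq_id,
                            "start": s,
                            "end": e,
                            "observed_unit": unit,
                            "canonical": canonical_label(unit),
                            "unit_length": len(unit),
                            "repeat_count": count,
                            "categories": ",".join(sorted(_categories_of(layout, s, e))),
                            "element_label": label or "",
                            "rel_value": value if value is not None else np.nan,
                            "bin": position_bin(value) if value is not None else "",
                            "chain_id": req_idx if len(members) > 1 else -1,
                        }
                    )
                    cursor = e
                    if mi < len(req.chain_gaps):
                        cursor += req.chain_gaps[mi]
                placed = True
                break
            if placed:
                break
        if not placed:
            raise SimulationError(
                f"could not place request #{req_idx} (target {req.target!r}, "
                f"{block_len} bp) without violating separation constraints"
            )

    sequences = {}
    for layout in layouts:
        sequences[layout.seq_id] = _verify_and_fix(
            arrays[layout.seq_id], expected[layout.seq_id],
            blocked[layout.seq_id], config.thresholds, rng,
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "seq_id", "start", "end", "observed_unit", "canonical",
            "unit_length", "repeat_count", "categories", "element_label",
            "rel_value", "bin", "chain_id",
        ],
    ).sort_values(["seq_id", "start"]).reset_index(drop=True)
    return SimulatedGenome(
        config=config, sequences=sequences, layouts=layouts, truth=truth
    )


def _write_chain(
    arr: np.ndarray,
    start: int,
    members: tuple[tuple[str, int], ...],
    gaps: tuple[int, ...],
    rng: np.random.Generator,
) -> None:
    cursor = start
    for mi, (unit, count) in enumerate(members):
        repeat = (unit * count).encode("ascii")
        end = cursor + len(repeat)
        arr[cursor:end] = np.frombuffer(repeat, dtype=np.uint8)
        # flanking bases must not extend the run by even a partial unit
        left, right = ord(unit[-1]), ord(unit[0])
        if cursor - 1 >= 0 and arr[cursor - 1] == left:
            arr[cursor - 1] = rng.choice(_BASES[_BASES != left])
        if end < len(arr) and arr[end] == right:
            arr[end] = rng.choice(_BASES[_BASES != right])
        cursor = end
        if mi < len(gaps):
            cursor += gaps[mi]


def _verify_and_fix(
    arr: np.ndarray,
    expected: set[tuple[int, int, str]],
    blocked: list[iv.Interval],
    thresholds: MiningThresholds,
    rng: np.random.Generator,
) -> str:
    """Break any incidental SSR the planting created, to a fixed point."""
    protected = iv.merge(
        [(s - 1, e + 1) for s, e, _ in expected]
    )
    for _ in range(50):
        seq = arr.tobytes().decode("ascii")
        mined = {
            (r.start, r.end, r.observed_unit) for r in find_perfect_ssrs(seq, thresholds)
        }
        extra = mined - expected
        if not extra and expected <= mined:
            return seq
        if not extra:
            raise SimulationError(
                f"planted SSRs not recovered: {sorted(expected - mined)[:3]}"
            )
        for s, e, _unit in extra:
            positions = [
                p
                for p in range(s, e)
                if arr[p] != ord("N") and not iv.overlaps_any(protected, p, p + 1)
            ]
            if not positions:
                raise SimulationError("incidental SSR overlaps a planted repeat")
            pos = positions[len(positions) // 2]
            arr[pos] = rng.choice(_BASES[_BASES != arr[pos]])
    raise SimulationError("planting cleanup did not converge")


# ---------------------------------------------------------------------------
# config (de)serialization and the standard benchmark


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "seed": config.seed,
        "flank": config.flank,
        "min_exons": config.min_exons,
        "thresholds": config.thresholds.to_definition(),
        "compound_gap": config.thresholds.compound_max_gap,
        "sequences": [
            {
                "seq_id": p.seq_id,
                "gaps": list(p.gaps),
                "n_run": p.n_run,
                "genes": [
                    {
                        "exon_lengths": list(g.exon_lengths),
                        "intron_lengths": list(g.intron_lengths),
                        "strand": g.strand,
                        "utr5": g.utr5,
                        "utr3": g.utr3,
                    }
                    for g in p.genes
                ],
            }
            for p in config.sequences
        ],
        "plants": [
            {
                "unit": r.unit,
                "repeat_count": r.repeat_count,
                "target": r.target,
                "rel_position": r.rel_position,
                "chain": [list(m) for m in r.chain],
                "chain_gaps": list(r.chain_gaps),
            }
            for r in config.plants
        ],
    }


def config_from_dict(data: dict) -> SimulationConfig:
    thresholds = MiningThresholds.from_definition(
        data.get("thresholds", "1-12,2-6,3-5,4-5,5-4,6-4"),
        compound_max_gap=data.get("compound_gap", 100),
    )
    sequences = tuple(
        SequencePlan(
            seq_id=p["seq_id"],
            gaps=tuple(p["gaps"]),
            n_run=p.get("n_run", 0),
            genes=tuple(
                GeneTemplate(
                    exon_lengths=tuple(g["exon_lengths"]),
                    intron_lengths=tuple(g["intron_lengths"]),
                    strand=g.get("strand", "+"),
                    utr5=g.get("utr5", 60),
                    utr3=g.get("utr3", 60),
                )
                for g in p["genes"]
            ),
        )
        for p in data["sequences"]
    )
    plants = tuple(
        PlantRequest(
            unit=r.get("unit", ""),
            repeat_count=r.get("repeat_count", 0),
            target=r.get("target", "intergenic"),
            rel_position=r.get("rel_position"),
            chain=tuple((u, c) for u, c in r.get("chain", [])),
            chain_gaps=tuple(r.get("chain_gaps", [])),
        )
        for r in data["plants"]
    )
    return SimulationConfig(
        seed=int(data["seed"]),
        sequences=sequences,
        plants=plants,
        thresholds=thresholds,
        flank=data.get("flank", 500),
        min_exons=data.get("min_exons", 7),
    )


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# palette of planted units covering all unit lengths and both strand
# spellings (CTT is the AAG class read from the other strand, etc.)
_UNIT_PALETTE: tuple[tuple[str, int], ...] = (
    ("A", 14), ("T", 13), ("AG", 8), ("GT", 9), ("AAT", 6), ("CTT", 7),
    ("AAAC", 5), ("TTTA", 6), ("AACAA", 5), ("TTGTT", 4), ("AAACAA", 4),
    ("GAGAGG", 5),
)


def benchmark_config(seed: int, n_ssrs: int = 230) -> SimulationConfig:
    """The standard study-scale benchmark: ~1.1 Mb, >= 200 planted SSRs.

    Two sequences; nine profiled genes (7-11 exons) on both strands plus a
    3-exon and a 6-exon gene (the latter sits exactly below the 7-exon
    profiling cutoff); N runs in both sequences; plants covering all six
    unit lengths, every region category and all 13 gene-element labels,
    pinned relative positions in every tenth bin, and one explicit
    two-member chain 50 bp apart (a compound SSR).
    """
    rng = np.random.default_rng(seed)

    def gene(n_exons: int, strand: str) -> GeneTemplate:
        exons = tuple(int(x) for x in rng.integers(240, 400, size=n_exons))
        introns = tuple(int(x) for x in rng.integers(700, 1200, size=n_exons - 1))
        return GeneTemplate(exons, introns, strand=strand, utr5=70, utr3=70)

    seq1_genes = (gene(7, "+"), gene(8, "-"), gene(9, "+"), gene(10, "-"),
                  gene(7, "+"), gene(3, "-"))
    seq2_genes = (gene(7, "-"), gene(9, "+"), gene(8, "-"), gene(11, "+"),
                  gene(6, "+"))
    seq1 = SequencePlan(
        "chrSim1", seq1_genes, gaps=(60_000,) + (75_000,) * 5 + (80_000,), n_run=400
    )
    seq2 = SequencePlan(
        "chrSim2", seq2_genes, gaps=(60_000,) + (80_000,) * 4 + (90_000,), n_run=250
    )

    plants: list[PlantRequest] = []

    def unit_for(i: int) -> tuple[str, int]:
        return _UNIT_PALETTE[i % len(_UNIT_PALETTE)]

    i = 0
    # every element label, several times with varied units
    for label in ELEMENT_LABELS:
        for _ in range(4):
            u, c = unit_for(i)
            i += 1
            plants.append(PlantRequest(unit=u, repeat_count=c, target=label))
    # pinned relative positions spanning every tenth bin
    for j, rel in enumerate([k / 10 for k in range(0, 10)] + [0.95, 1.0]):
        u, c = unit_for(i)
        i += 1
        plants.append(
            PlantRequest(
                unit=u, repeat_count=c,
                target=("intron1", "intron2", "last2_intron", "last_intron")[j % 4],
                rel_position=rel,
            )
        )
    # region-category plants (intergenic bulk + gene-region coverage)
    for target, n in (("intergenic", 110), ("intron", 30), ("CDS", 12), ("UTR", 8)):
        for _ in range(n):
            u, c = unit_for(i)
            i += 1
            if target == "CDS":
                u, c = ("AAT", 6) if i % 2 else ("AAACAA", 4)
            plants.append(PlantRequest(unit=u, repeat_count=c, target=target))
    # one explicit compound: two runs 50 bp apart
    plants.append(
        PlantRequest(target="intergenic", chain=(("A", 14), ("AG", 8)),
                     chain_gaps=(50,))
    )
    if len(plants) < n_ssrs:
        for _ in range(n_ssrs - len(plants)):
            u, c = unit_for(i)
            i += 1
            plants.append(PlantRequest(unit=u, repeat_count=c, target="intergenic"))
    return SimulationConfig(
        seed=seed, sequences=(seq1, seq2), plants=tuple(plants)
    )
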
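"""Readers and writers for SSR tables and annotation output.

Two tabular formats are produced:

* a MISA-style TSV (``ID``, ``SSR nr.``, ``SSR type``, ``SSR``, ``size``,
  ``start``, ``end``) with 1-based inclusive coordinates, for
  interoperability with MISA-era tooling; compound SSRs appear as extra
  rows of type ``c`` spanning their members;
* a machine-oriented SSR TSV (0-based half-open coordinates, canonical
  class, repeat count) that round-trips through :func:`read_ssr_tsv` and is
  the interchange format between pipeline stages.

SSR features can also be written as GFF3 ``microsatellite`` records.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .mining import CompoundSSR, SSRRecord

SSR_TSV_COLUMNS = (
    "seq_id", "start", "end", "observed_unit", "canonical",
    "unit_length", "repeat_count",
)


def write_ssr_tsv(records: list[SSRRecord], path: str | Path) -> None:
    """Machine-oriented SSR table; coordinates 0-based half-open."""
    frame = pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "observed_unit": r.observed_unit,
                "canonical": r.canonical,
                "unit_length": r.unit_length,
                "repeat_count": r.repeat_count,
            }
            for r in records
        ],
        columns=list(SSR_TSV_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


def read_ssr_tsv(path: str | Path) -> list[SSRRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    return [
        SSRRecord(
            seq_id=row.seq_id,
            start=int(row.start),
            end=int(row.end),
            observed_unit=row.observed_unit,
            canonical=row.canonical,
            unit_length=int(row.unit_length),
            repeat_count=int(row.repeat_count),
        )
        for row in frame.itertuples()
    ]


def write_misa_tsv(
    records: list[SSRRecord],
    path: str | Path,
    compounds: list[CompoundSSR] | None = None,
) -> None:
    """MISA-style table: 1-based inclusive coordinates, type p1..p6 / c."""
    rows = []
    nr = 0
    for r in records:
        nr += 1
        rows.append(
            {
                "ID": r.seq_id,
                "SSR nr.": nr,
                "SSR type": f"p{r.unit_length}",
                "SSR": r.as_misa_motif(),
                "size": r.length,
                "start": r.start + 1,
                "end": r.end,
            }
        )
    for c in compounds or []:
        nr += 1
        rows.append(
            {
                "ID": c.seq_id,
                "SSR nr.": nr,
                "SSR type": "c",
                "SSR": "*".join(m.as_misa_motif() for m in c.members),
                "size": c.span_end - c.span_start,
                "start": c.span_start + 1,
                "end": c.span_end,
            }
        )
    pd.DataFrame(
        rows, columns=["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"]
    ).to_csv(path, sep="\t", index=False)


def write_ssr_gff3(
    records: list[SSRRecord],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """SSRs as GFF3 ``microsatellite`` features with class/repeat attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, length in (seq_lengths or {}).items():
            fh.write(f"##sequence-region {sid} 1 {length}\n")
        for i, r in enumerate(records, start=1):
            attrs = (
                f"ID=ssr{i:06d};Motif={r.observed_unit};"
                f"Class={r.canonical};Repeats={r.repeat_count}"
            )
            fh.write(
                f"{r.seq_id}\tssrscape\tmicrosatellite\t{r.start + 1}\t{r.end}"
                f"\t.\t+\t.\t{attrs}\n"
            )


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    from .mining import iter_fasta

    return {sid: len(seq) for sid, seq in iter_fasta(path)}


def read_gff3_sequence_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths from ``##sequence-region`` pragmas, if present."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, sid, _start, end = line.split()[:4]
                out[sid] = int(end)
            elif not line.startswith("#"):
                break
    return out
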
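"""Small interval-arithmetic helpers on 0-based half-open ``(start, end)`` pairs.

All functions expect and return plain lists of tuples; merged outputs are
sorted and pairwise disjoint.
"""

from __future__ import annotations

from bisect import bisect_right

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint list (empty intervals dropped)."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Set difference ``a - b`` (both merged first)."""
    a, b = merge(a), merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def complement(intervals: list[Interval], length: int) -> list[Interval]:
    """Complement of intervals within ``[0, length)``."""
    return subtract([(0, length)], intervals)


def total_length(intervals: list[Interval]) -> int:
    """Summed length of a *merged* interval list."""
    return sum(e - s for s, e in intervals)


def overlaps_any(merged: list[Interval], start: int, end: int) -> bool:
    """True iff ``[start, end)`` overlaps a merged, sorted interval list by >= 1 bp."""
    i = bisect_right(merged, (start, float("inf"))) - 1
    if i >= 0 and merged[i][1] > start:
        return True
    return i + 1 < len(merged) and merged[i + 1][0] < end


def containing(merged: list[Interval], start: int, end: int) -> Interval | None:
    """The merged interval fully containing ``[start, end)``, if any."""
    i = bisect_right(merged, (start, float("inf"))) - 1
    if i >= 0 and merged[i][0] <= start and end <= merged[i][1]:
        return merged[i]
    return None


def overlap_length(merged: list[Interval], start: int, end: int) -> int:
    """Total overlap (bp) between ``[start, end)`` and a merged interval list."""
    out = 0
    for s, e in merged:
        if s >= end:
            break
        out += max(0, min(e, end) - max(s, start))
    return out
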
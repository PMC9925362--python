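"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's scanning and class-enumeration code
paths: the repeat scanner tries every (start, unit-length) pair and extends
by literal slice comparison; the class counter is a union-find over all
4^k strings.  Both implement the same published conventions the package
documents (left-anchored whole-unit records; overlap resolution by earliest
start, then shortest unit).
"""

from __future__ import annotations

DEFAULT_MIN_REPEATS = {1: 12, 2: 6, 3: 5, 4: 5, 5: 4, 6: 4}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_ssrs(sequence: str, min_repeats=None) -> list[tuple[int, int, str, int]]:
    """Every maximal perfect SSR as (start, end, unit, count), by exhaustion."""
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    seq = sequence.upper()
    n = len(seq)
    candidates = []
    for start in range(n):
        for k, min_rep in min_repeats.items():
            unit = seq[start : start + k]
            if len(unit) < k or any(ch not in "ACGT" for ch in unit):
                continue
            if any(unit == unit[:d] * (k // d) for d in range(1, k) if k % d == 0):
                continue  # non-primitive
            if start >= k and seq[start - k : start] == unit:
                continue  # extendable left by a whole unit
            count = 1
            while seq[start + count * k : start + (count + 1) * k] == unit:
                count += 1
            if count >= min_rep:
                candidates.append((start, k, count, unit))
    candidates.sort(key=lambda c: (c[0], c[1]))
    out: list[tuple[int, int, str, int]] = []
    frontier = 0
    for a, k, c, u in candidates:
        if out and a < frontier:
            continue
        out.append((a, a + k * c, u, c))
        frontier = a + k * c
    return out


def _reverse_complement(s: str) -> str:
    return "".join(_RC[ch] for ch in reversed(s))


def union_find_class_count(k: int) -> int:
    """Number of rotation/reverse-complement classes of primitive k-mers."""
    import itertools

    strings = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    primitive = [
        s
        for s in strings
        if all(s != s[:d] * (k // d) for d in range(1, k) if k % d == 0)
    ]
    index = {s: i for i, s in enumerate(primitive)}
    parent = list(range(len(primitive)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for s, i in index.items():
        union(i, index[s[1:] + s[0]])          # rotate by one
        union(i, index[_reverse_complement(s)])  # opposite strand
    return len({find(i) for i in range(len(primitive))})
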
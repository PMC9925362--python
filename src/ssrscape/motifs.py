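"""Repeat-unit algebra: rotations, reverse complements and canonical motif classes.

A microsatellite repeat unit (1-6 bp over A/C/G/T) is identified with every
cyclic rotation of itself and of its reverse complement: ``(AAG)n``,
``(GAA)n`` and ``(CTT)n`` all describe the same tandem repeat read in a
different frame or from the opposite strand.  The resulting equivalence
class is labelled by its lexicographically smallest member, which gives a
deterministic, comparison-friendly name (the AAG class, the AC class, ...).

Only *primitive* units are classed: a unit that is itself a whole-number
repetition of a shorter unit (``ATAT`` = ``AT`` x 2) never names a class,
because the repeat it describes is already a repeat of the shorter unit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

MAX_UNIT_LENGTH = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ALPHABET = frozenset("ACGT")


class MotifError(ValueError):
    """Base class for repeat-unit errors."""


class InvalidMotifError(MotifError):
    """Unit is empty, too long, or contains a non-ACGT character."""


class NonPrimitiveMotifError(MotifError):
    """Unit is a whole-number repetition of a shorter unit."""


def normalize_unit(unit: str) -> str:
    """Uppercase ``unit`` and validate alphabet and length (1-6 bp).

    Lowercase input is accepted because soft-masked genome sequence is
    commonplace; anything outside A/C/G/T is rejected.
    """
    u = unit.upper()
    if not 1 <= len(u) <= MAX_UNIT_LENGTH:
        raise InvalidMotifError(
            f"repeat unit must be 1-{MAX_UNIT_LENGTH} bp, got {len(u)} ({unit!r})"
        )
    if not _ALPHABET.issuperset(u):
        raise InvalidMotifError(f"repeat unit contains non-ACGT characters: {unit!r}")
    return u


def reverse_complement(unit: str) -> str:
    """Watson-Crick complement of ``unit``, reversed.

    An involution: ``reverse_complement(reverse_complement(u)) == u``.
    """
    return normalize_unit(unit).translate(_COMPLEMENT)[::-1]


def rotations(unit: str) -> frozenset[str]:
    """All cyclic shifts of ``unit``.

    For a primitive unit of length k there are exactly k distinct
    rotations; in general the count divides k.
    """
    u = normalize_unit(unit)
    return frozenset(u[i:] + u[:i] for i in range(len(u)))


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number repetition of a shorter unit."""
    u = normalize_unit(unit)
    n = len(u)
    return all(u != u[:d] * (n // d) for d in range(1, n) if n % d == 0)


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of a repeat unit under rotation + reverse complement.

    ``canonical`` is the lexicographically smallest member and serves as the
    class label.  ``members`` is closed under both operations and contains at
    most ``2 * unit_length`` units.
    """

    canonical: str
    members: frozenset[str]

    @property
    def unit_length(self) -> int:
        return len(self.canonical)

    def __contains__(self, unit: str) -> bool:
        return normalize_unit(unit) in self.members

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.canonical}-class({len(self.members)} members)"


@lru_cache(maxsize=None)
def canonical_class(unit: str) -> MotifClass:
    """The motif class of a primitive ``unit``.

    Members are ``rotations(unit) | rotations(reverse_complement(unit))``.
    Two units land in equal classes iff one is a rotation of the other or of
    its reverse complement.  Non-primitive units are rejected: classing them
    would double-count the repeat they alias.
    """
    u = normalize_unit(unit)
    if not is_primitive(u):
        raise NonPrimitiveMotifError(
            f"{unit!r} is a repetition of a shorter unit and has no class of its own"
        )
    members = rotations(u) | rotations(reverse_complement(u))
    return MotifClass(canonical=min(members), members=members)


def canonical_label(unit: str) -> str:
    """Shorthand for ``canonical_class(unit).canonical``."""
    return canonical_class(unit).canonical


def enumerate_classes(unit_length: int) -> list[MotifClass]:
    """All motif classes of primitive units of ``unit_length``, sorted by label.

    The classes partition the primitive units: every primitive k-mer belongs
    to exactly one returned class.  Counts for k = 1..6 are 2, 4, 10, 33,
    102 and 350.
    """
    if not 1 <= unit_length <= MAX_UNIT_LENGTH:
        raise InvalidMotifError(
            f"unit length must be 1-{MAX_UNIT_LENGTH}, got {unit_length}"
        )
    seen: set[str] = set()
    classes: list[MotifClass] = []
    for chars in itertools.product("ACGT", repeat=unit_length):
        u = "".join(chars)
        if u in seen or not is_primitive(u):
            continue
        cls = canonical_class(u)
        seen.update(cls.members)
        classes.append(cls)
    classes.sort(key=lambda c: c.canonical)
    return classes
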
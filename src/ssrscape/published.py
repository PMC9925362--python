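"""Published genome-wide SSR counts for two bat genomes, used as inputs.

A comparative survey of microsatellites in the assemblies of *Pteropus
vampyrus* (Pvam_2.0, ~2.20 Gb) and *Miniopterus natalensis* (Mnat.v1,
~1.80 Gb) reports per-unit-length SSR counts and summed lengths, and the
counts of the four most frequent motif classes per unit length.  Those raw
counts and the whole-genome lengths are recorded here as *inputs*: the
derived quantities (abundance in SSRs/Mb, frequency percentages, SSR
content) are never stored — they are recomputed by :mod:`ssrscape.stats`
from these counts, which is exactly the arithmetic the survey tables print.

Motif classes are keyed by the representative spelling the survey uses
(e.g. ``CT`` for the AG class); :func:`ssrscape.motifs.canonical_label`
maps any spelling to the canonical class name.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping


@dataclass(frozen=True)
class PublishedGenomeSurvey:
    """Raw published counts for one genome.

    ``unit_counts``/``unit_lengths_bp`` map unit length (1-6) to SSR count
    and summed SSR length; ``motif_counts`` maps unit length to the
    reported per-class counts (top four classes, except mononucleotides
    where both classes are reported).
    """

    name: str
    genome_length_bp: int
    unit_counts: Mapping[int, int]
    unit_lengths_bp: Mapping[int, int]
    motif_counts: Mapping[int, Mapping[str, int]]


PTEROPUS_VAMPYRUS = PublishedGenomeSurvey(
    name="Pteropus vampyrus",
    genome_length_bp=2_198_284_804,
    unit_counts=MappingProxyType(
        {1: 246_947, 2: 163_249, 3: 36_521, 4: 43_966, 5: 15_137, 6: 6_827}
    ),
    unit_lengths_bp=MappingProxyType(
        {1: 3_647_964, 2: 3_649_342, 3: 750_138, 4: 1_409_268, 5: 382_635, 6: 199_332}
    ),
    motif_counts=MappingProxyType(
        {
            1: MappingProxyType({"A": 241_850, "G": 5_097}),
            2: MappingProxyType(
                {"AC": 95_909, "CT": 37_060, "GC": 1_394, "TA": 28_886}
            ),
            3: MappingProxyType(
                {"CAA": 11_151, "TAT": 9_997, "CAT": 4_202, "GAG": 2_974}
            ),
            4: MappingProxyType(
                {"AAAC": 10_035, "ATAG": 6_429, "CATT": 5_268, "TTTA": 4_488}
            ),
            5: MappingProxyType(
                {"AACAA": 8_277, "TTATT": 2_174, "TTTCT": 851, "CCACC": 295}
            ),
            6: MappingProxyType(
                {"AAACAA": 1_561, "GGGTTA": 1_282, "CTGTCT": 442, "TATCTA": 414}
            ),
        }
    ),
)

MINIOPTERUS_NATALENSIS = PublishedGenomeSurvey(
    name="Miniopterus natalensis",
    genome_length_bp=1_803_099_001,
    unit_counts=MappingProxyType(
        {1: 144_835, 2: 235_344, 3: 20_959, 4: 32_493, 5: 10_320, 6: 4_723}
    ),
    unit_lengths_bp=MappingProxyType(
        {1: 2_174_691, 2: 4_030_076, 3: 386_283, 4: 1_259_172, 5: 367_900, 6: 188_970}
    ),
    motif_counts=MappingProxyType(
        {
            1: MappingProxyType({"A": 133_249, "G": 11_586}),
            2: MappingProxyType(
                {"AC": 80_208, "CT": 126_869, "GC": 467, "TA": 27_800}
            ),
            3: MappingProxyType(
                {"TAT": 8_458, "CAA": 3_341, "CAT": 2_508, "ACC": 2_380}
            ),
            4: MappingProxyType(
                {"TTTA": 7_092, "ATAG": 5_488, "CATT": 3_802, "CCTT": 3_721}
            ),
            5: MappingProxyType(
                {"AACAA": 2_623, "TTATT": 2_515, "TTTCT": 621, "AGGGA": 606}
            ),
            6: MappingProxyType(
                {"GAGAGG": 604, "TATCTA": 271, "CTGTCT": 261, "GGGTTA": 215}
            ),
        }
    ),
)

SURVEYS = {s.name: s for s in (PTEROPUS_VAMPYRUS, MINIOPTERUS_NATALENSIS)}
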
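"""Summary-table arithmetic: abundance, frequency, content, rankings."""

import numpy as np
import pytest

from ssrscape.mining import SSRRecord
from ssrscape.published import MINIOPTERUS_NATALENSIS, PTEROPUS_VAMPYRUS
from ssrscape.stats import (
    GenomeSummary,
    compare_genomes,
    motif_class_summary,
    motif_class_summary_from_counts,
    round_half_up,
    top_k_classes,
    unit_length_summary,
    unit_length_summary_from_counts,
)

# printed derived columns of the published bat survey (2-decimal half-up):
# per unit length 1-6: abundance (SSRs/Mb) and frequency (% of all SSRs),
# then total abundance and SSR content (%)
PRINTED = {
    "Pteropus vampyrus": {
        "abundance": [112.34, 74.26, 16.61, 20.00, 6.89, 3.11],
        "frequency": [48.17, 31.84, 7.12, 8.58, 2.95, 1.33],
        "total_abundance": 233.20,
        "content_pct": 0.46,
        "motif_pct": {
            1: {"A": 97.94, "G": 2.06},
            2: {"AC": 58.75, "CT": 22.70, "GC": 0.85, "TA": 17.69},
            3: {"CAA": 30.53, "TAT": 27.37, "CAT": 11.51, "GAG": 8.14},
            4: {"AAAC": 22.82, "ATAG": 14.62, "CATT": 11.98, "TTTA": 10.21},
            5: {"AACAA": 54.68, "TTATT": 14.36, "TTTCT": 5.62, "CCACC": 1.95},
            6: {"AAACAA": 22.87, "GGGTTA": 18.78, "CTGTCT": 6.47, "TATCTA": 6.06},
        },
    },
    "Miniopterus natalensis": {
        "abundance": [80.33, 130.52, 11.62, 18.02, 5.72, 2.62],
        "frequency": [32.28, 52.45, 4.67, 7.24, 2.30, 1.05],
        "total_abundance": 248.83,
        "content_pct": 0.47,
        "motif_pct": {
            1: {"A": 92.00, "G": 8.00},
            2: {"AC": 34.08, "CT": 53.91, "GC": 0.20, "TA": 11.81},
            3: {"TAT": 40.36, "CAA": 15.94, "CAT": 11.97, "ACC": 11.36},
            4: {"TTTA": 21.83, "ATAG": 16.89, "CATT": 11.70, "CCTT": 11.45},
            5: {"AACAA": 25.42, "TTATT": 24.37, "TTTCT": 6.02, "AGGGA": 5.87},
            6: {"GAGAGG": 12.79, "TATCTA": 5.74, "CTGTCT": 5.53, "GGGTTA": 4.55},
        },
    },
}

SURVEYS = {s.name: s for s in (PTEROPUS_VAMPYRUS, MINIOPTERUS_NATALENSIS)}


def test_round_half_up_behaviour():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(0.124) == 0.12
    assert round_half_up(233.195) == 233.20


@pytest.mark.parametrize("name", list(SURVEYS))
def test_unit_length_arithmetic_reproduces_published_derived_columns(name):
    survey = SURVEYS[name]
    frame = unit_length_summary_from_counts(
        survey.unit_counts, survey.unit_lengths_bp, survey.genome_length_bp
    )
    printed = PRINTED[name]
    for k in range(1, 7):
        assert round_half_up(frame.loc[k, "abundance_ssrs_per_mb"]) == printed["abundance"][k - 1]
        assert round_half_up(frame.loc[k, "frequency_of_total_pct"]) == printed["frequency"][k - 1]
    assert round_half_up(frame.loc["total", "abundance_ssrs_per_mb"]) == printed["total_abundance"]
    assert round_half_up(frame.loc["total", "frequency_of_total_pct"]) == 100.00
    assert round_half_up(frame.attrs["ssr_content_pct"]) == printed["content_pct"]


@pytest.mark.parametrize("name", list(SURVEYS))
def test_motif_class_arithmetic_reproduces_published_percentages(name):
    survey = SURVEYS[name]
    frame = motif_class_summary_from_counts(
        survey.motif_counts, unit_totals=survey.unit_counts
    )
    printed = PRINTED[name]["motif_pct"]
    for row in frame.itertuples():
        expected = printed[row.unit_length][row.class_label]
        # agreement to the printed precision (one published value, TAT at
        # 8458/20959 = 40.3550%, was evidently double-rounded to 40.36)
        assert round_half_up(row.frequency_within_unit_pct) == pytest.approx(
            expected, abs=0.01
        )


@pytest.mark.parametrize("name", list(SURVEYS))
def test_summary_internal_invariants(name):
    survey = SURVEYS[name]
    frame = unit_length_summary_from_counts(
        survey.unit_counts, survey.unit_lengths_bp, survey.genome_length_bp
    )
    units = frame.drop(index="total")
    assert units["count"].sum() == frame.loc["total", "count"]
    assert units["abundance_ssrs_per_mb"].sum() == pytest.approx(
        frame.loc["total", "abundance_ssrs_per_mb"]
    )
    assert units["frequency_of_total_pct"].sum() == pytest.approx(100.0, abs=0.03)


def _records(spec):
    """spec: list of (unit, count, n_records) -> synthetic SSRRecord list."""
    out = []
    pos = 0
    from ssrscape.motifs import canonical_label

    for unit, count, n in spec:
        for _ in range(n):
            out.append(
                SSRRecord(
                    "s", pos, pos + len(unit) * count, unit,
                    canonical_label(unit), len(unit), count,
                )
            )
            pos += len(unit) * count + 200
    return out


def test_unit_summary_from_records_and_permutation_invariance():
    recs = _records([("A", 12, 3), ("AG", 6, 2), ("AAT", 5, 1)])
    frame = unit_length_summary(recs, genome_length=1_000_000)
    assert frame.loc[1, "count"] == 3
    assert frame.loc[2, "count"] == 2
    assert frame.loc["total", "count"] == 6
    assert frame.loc[1, "abundance_ssrs_per_mb"] == pytest.approx(3.0)
    assert frame.loc[1, "total_length_bp"] == 36

    rng = np.random.default_rng(0)
    shuffled = list(recs)
    rng.shuffle(shuffled)
    assert unit_length_summary(shuffled, 1_000_000).equals(frame)


def test_empty_ssr_list_gives_zero_summary():
    frame = unit_length_summary([], genome_length=1000)
    assert frame["count"].sum() == 0
    assert frame.loc["total", "frequency_of_total_pct"] == 0.0
    assert frame.attrs["ssr_content_pct"] == 0.0


def test_zero_genome_length_rejected():
    with pytest.raises(ValueError):
        unit_length_summary([], genome_length=0)


def test_motif_class_summary_counts_classes_not_spellings():
    # CTT and AAG are the same class; observed_label keeps the majority spelling
    recs = _records([("CTT", 5, 3), ("AAG", 5, 1), ("A", 12, 1)])
    frame = motif_class_summary(recs)
    tri = frame[frame["unit_length"] == 3]
    assert list(tri["class_label"]) == ["AAG"]
    assert int(tri["count"].iloc[0]) == 4
    assert tri["frequency_within_unit_pct"].iloc[0] == pytest.approx(100.0)
    assert tri["observed_label"].iloc[0] == "CTT"


def test_single_class_is_100_percent():
    frame = motif_class_summary(_records([("AC", 8, 5)]))
    assert frame["frequency_within_unit_pct"].iloc[0] == pytest.approx(100.0)


class TestTopK:
    def test_exhaustive_k_reaches_100(self):
        frame = motif_class_summary(_records([("A", 12, 4), ("AC", 6, 3), ("AAT", 5, 2)]))
        top = top_k_classes(frame, k=len(frame))
        assert top["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_k1_single_class(self):
        frame = motif_class_summary(_records([("A", 12, 5)]))
        top = top_k_classes(frame, k=1)
        assert top["cumulative_pct"].iloc[0] == pytest.approx(100.0)

    def test_ranking_follows_planted_spectrum(self):
        frame = motif_class_summary(
            _records([("A", 12, 10), ("AC", 6, 7), ("AAT", 5, 2), ("AAAC", 5, 1)])
        )
        top = top_k_classes(frame, k=3)
        assert list(top["class_label"]) == ["A", "AC", "AAT"]
        assert top["cumulative_pct"].iloc[-1] == pytest.approx(100 * 19 / 20)

    def test_k_must_be_positive(self):
        frame = motif_class_summary(_records([("A", 12, 1)]))
        with pytest.raises(ValueError):
            top_k_classes(frame, k=0)


class TestCompare:
    def _summary(self, name, spec):
        recs = _records(spec)
        return GenomeSummary(
            name=name,
            unit_summary=unit_length_summary(recs, 1_000_000),
            class_summary=motif_class_summary(recs),
        )

    def test_self_comparison_has_no_unique_classes(self):
        a = self._summary("a", [("A", 12, 3), ("AC", 6, 2)])
        rep = compare_genomes(a, a)
        assert all(not v for v in rep.unique_to_a.values())
        assert all(not v for v in rep.unique_to_b.values())

    def test_single_differing_hexanucleotide_class(self):
        base = [("A", 12, 3), ("AAACAA", 4, 2)]
        a = self._summary("a", base)
        b = self._summary("b", [("A", 12, 3), ("GAGAGG", 4, 2)])
        rep = compare_genomes(a, b)
        from ssrscape.motifs import canonical_label

        assert rep.unique_to_a[6] == [canonical_label("AAACAA")]
        assert rep.unique_to_b[6] == [canonical_label("GAGAGG")]

    def test_disjoint_plantings_share_nothing(self):
        a = self._summary("a", [("A", 12, 3)])
        b = self._summary("b", [("AC", 6, 3)])
        rep = compare_genomes(a, b)
        assert all(not v for v in rep.shared_classes.values())

    def test_mismatched_thresholds_rejected(self):
        a = self._summary("a", [("A", 12, 1)])
        b = self._summary("b", [("A", 12, 1)])
        b.thresholds_definition = "1-10,2-6,3-5,4-5,5-4,6-4"
        with pytest.raises(ValueError, match="thresholds"):
            compare_genomes(a, b)
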
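"""13-element gene partition and relative-position statistics."""

import pytest

from ssrscape.mining import SSRRecord
from ssrscape.positions import (
    BINS,
    ELEMENT_LABELS,
    assign_elements,
    element_profile,
    partition_gene_elements,
    position_bin,
    relative_position,
    select_multiexon_genes,
)
from ssrscape.regions import GeneModel, Transcript


def make_gene(
    n_exons,
    strand="+",
    exon_len=100,
    intron_len=200,
    offset=2000,
    seq_id="s1",
    gene_id="g1",
):
    exons = []
    cur = offset
    for _ in range(n_exons):
        exons.append((cur, cur + exon_len))
        cur += exon_len + intron_len
    span = (offset, exons[-1][1])
    t = Transcript("t1", tuple(exons), cds=tuple(exons))
    return GeneModel(gene_id, seq_id, strand, span, (t,))


def _ssr(start, end, seq_id="s1"):
    return SSRRecord(seq_id, start, end, "A", "A", 1, end - start)


class TestSelection:
    def test_seven_exons_retained_six_excluded(self):
        genes = [make_gene(7, gene_id="keep"), make_gene(6, gene_id="drop")]
        assert [g.gene_id for g in select_multiexon_genes(genes)] == ["keep"]

    def test_representative_transcript_is_largest(self):
        g7 = make_gene(7)
        g_small = make_gene(4)
        combined = GeneModel(
            "g", "s1", "+", g7.span, (g_small.transcripts[0], g7.transcripts[0])
        )
        assert select_multiexon_genes([combined]) == [combined]


class TestPartition:
    def test_all_13_labels_present_and_disjoint(self):
        part = partition_gene_elements(make_gene(7), seq_length=10_000)
        assert set(part.elements) == set(ELEMENT_LABELS)
        ivs = sorted(i for v in part.elements.values() for i in v)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2  # pairwise disjoint

    def test_seven_exon_plus_strand_split(self):
        part = partition_gene_elements(make_gene(7), seq_length=10_000)
        # 3 middle exons: 2 left, 1 right (odd exon to the left half)
        assert len(part.elements["middle_left_exon"]) == 2
        assert len(part.elements["middle_right_exon"]) == 1
        assert len(part.elements["middle_intron"]) == 2

    def test_eight_exon_arithmetic(self):
        part = partition_gene_elements(make_gene(8), seq_length=10_000)
        assert len(part.elements["middle_left_exon"]) == 2
        assert len(part.elements["middle_right_exon"]) == 2
        assert len(part.elements["middle_intron"]) == 3

    def test_minus_strand_exon1_is_rightmost(self):
        gene = make_gene(7, strand="-")
        part = partition_gene_elements(gene, seq_length=10_000)
        rightmost = max(gene.transcripts[0].exons)
        assert part.elements["exon1"] == [rightmost]
        assert part.elements["last_exon"] == [gene.transcripts[0].exons[0]]
        # strand-aware flanks: upstream is genomically right of a minus gene
        assert part.elements["upstream500"][0][0] == gene.span[1]

    def test_upstream_clipped_at_sequence_start(self):
        part = partition_gene_elements(make_gene(7, offset=200), seq_length=10_000)
        assert part.elements["upstream500"] == [(0, 200)]

    def test_too_few_exons_rejected(self):
        with pytest.raises(ValueError, match="exons"):
            partition_gene_elements(make_gene(6), seq_length=10_000)


class TestRelativePosition:
    def test_flush_5prime(self):
        pos = relative_position(_ssr(100, 120), (100, 200), "+")
        assert pos.value == 0.0 and pos.bin == "P0.1"

    def test_flush_3prime(self):
        pos = relative_position(_ssr(180, 200), (100, 200), "+")
        assert pos.value == 1.0 and pos.bin == "P1.0"

    def test_methods_formula_midpoint(self):
        # element 100 bp, SSR 20 bp starting 40 bp in: 40 / (100 - 20) = 0.5
        pos = relative_position(_ssr(140, 160), (100, 200), "+")
        assert pos.value == pytest.approx(0.5) and pos.bin == "P0.5"

    def test_ssr_filling_element_gets_midpoint(self):
        pos = relative_position(_ssr(100, 200), (100, 200), "+")
        assert pos.value == 0.5

    def test_minus_strand_measures_from_3prime_boundary(self):
        plus = relative_position(_ssr(110, 130), (100, 200), "+")
        minus = relative_position(_ssr(110, 130), (100, 200), "-")
        assert plus.value == pytest.approx(10 / 80)
        assert minus.value == pytest.approx(70 / 80)

    def test_not_contained_rejected(self):
        with pytest.raises(ValueError, match="not contained"):
            relative_position(_ssr(90, 120), (100, 200), "+")

    def test_bin_boundaries_left_open_right_closed(self):
        assert position_bin(0.0) == "P0.1"
        assert position_bin(0.1) == "P0.1"
        assert position_bin(0.1000001) == "P0.2"
        assert position_bin(1.0) == "P1.0"
        assert [position_bin(i / 10) for i in range(1, 11)] == list(BINS)


def test_strand_mirror_leaves_relative_positions_unchanged():
    """Mirroring the whole locus to the opposite strand preserves values."""
    seq_len = 10_000
    gene = make_gene(7, strand="+")
    part = partition_gene_elements(gene, seq_len)
    ssr = _ssr(2040, 2060)  # inside exon1
    (a,) = assign_elements([ssr], [part])

    # mirror: coordinates x -> seq_len - x, strand flips
    m_exons = tuple(
        sorted((seq_len - e, seq_len - s) for s, e in gene.transcripts[0].exons)
    )
    m_gene = GeneModel(
        "g1m", "s1", "-", (seq_len - gene.span[1], seq_len - gene.span[0]),
        (Transcript("t1m", m_exons, m_exons),),
    )
    m_part = partition_gene_elements(m_gene, seq_len)
    m_ssr = _ssr(seq_len - 2060, seq_len - 2040)
    (b,) = assign_elements([m_ssr], [m_part])

    assert a.label == b.label
    assert a.position.value == pytest.approx(b.position.value)
    assert a.position.bin == b.position.bin


class TestProfile:
    def test_flank_only_planting_recovered(self):
        gene = make_gene(7)
        part = partition_gene_elements(gene, seq_length=10_000)
        up = part.elements["upstream500"][0]
        down = part.elements["downstream500"][0]
        ssrs = [_ssr(up[0] + 10, up[0] + 30), _ssr(down[0] + 50, down[0] + 70)]
        prof = element_profile(ssrs, [part])
        assert prof.counts["upstream500"] == 1
        assert prof.counts["downstream500"] == 1
        assert sum(prof.counts.values()) == 2

    def test_boundary_spanner_majority_rule_without_bin(self):
        gene = make_gene(7)
        part = partition_gene_elements(gene, seq_length=10_000)
        # exon1 = [2000, 2100), intron1 = [2100, 2300): 15 bp exon / 5 bp intron
        assignments = assign_elements([_ssr(2085, 2105)], [part])
        (a,) = assignments
        assert a.label == "exon1"
        assert a.position is None

    def test_boundary_tie_goes_5prime(self):
        gene = make_gene(7)
        part = partition_gene_elements(gene, seq_length=10_000)
        (a,) = assign_elements([_ssr(2090, 2110)], [part])
        assert a.label == "exon1"

    def test_bin_counts_sum_to_contained_counts(self):
        gene = make_gene(7)
        part = partition_gene_elements(gene, seq_length=10_000)
        ssrs = [_ssr(2000 + 12 * i, 2012 + 12 * i) for i in range(7)]  # in exon1
        prof = element_profile(ssrs, [part])
        per_label_bins = {}
        for (label, _bin), n in prof.bin_counts.items():
            per_label_bins[label] = per_label_bins.get(label, 0) + n
        assert per_label_bins["exon1"] == prof.counts["exon1"] == 7

    def test_abundance_is_count_per_mb(self):
        gene = make_gene(7)
        part = partition_gene_elements(gene, seq_length=10_000)
        prof = element_profile([_ssr(2010, 2030)], [part])
        assert prof.abundance("exon1") == pytest.approx(1 / (100 / 1e6))


def test_benchmark_element_truth_recovered(benchmark_sim, benchmark_paths):
    """On the synthetic benchmark, element labels and bins equal the truth table."""
    from ssrscape import build_gene_models, mine_genome

    result = mine_genome(benchmark_paths["fasta"])
    genes = select_multiexon_genes(build_gene_models(str(benchmark_paths["gff3"])))
    parts = [
        partition_gene_elements(g, result.seq_lengths[g.seq_id]) for g in genes
    ]
    assigned = {
        (a.ssr.seq_id, a.ssr.start): (a.label, a.position.bin if a.position else "")
        for a in assign_elements(result.records, parts)
    }
    truth = benchmark_sim.truth
    for row in truth.itertuples():
        got = assigned.get((row.seq_id, row.start), ("", ""))
        assert got[0] == (row.element_label or ""), row
        assert got[1] == (row.bin or ""), row
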
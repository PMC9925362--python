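# Methods

## Repeat model and mining

A microsatellite is modelled as a maximal perfect tandem run of a
*primitive* unit of length k ∈ {1…6} over A/C/G/T. Primitivity means the
unit is not a whole-number repetition of a shorter unit; a run of 12 A's is
one mononucleotide SSR and never additionally an (AA)₆ dinucleotide, which
prevents double counting. A run qualifies when its whole-unit repeat count
meets the per-unit-length minimum; the defaults

    k:          1   2   3   4   5   6
    min units: 12   6   5   5   4   4

are the MISA-style definition string `1-12,2-6,3-5,4-5,5-4,6-4`
(`MiningThresholds.from_definition`). Conventions:

* **Whole-unit records.** Records are anchored at the left end of the
  character-level run and span whole units only; a trailing partial unit
  neither counts toward the repeat number nor extends the span.
* **Maximality.** A reported record cannot be extended by one full unit on
  either side. This follows from the run-anchoring: the position before
  the run start and the positions after the last whole unit break the
  periodicity.
* **Hard breaks.** `N` and any other non-ACGT character terminates runs
  (it never raises); lowercase (soft-masked) sequence is uppercased.
* **Overlap resolution.** Maximal runs of different unit lengths can
  overlap by a few bases in pathological sequences. So that every genomic
  position belongs to at most one reported SSR, candidates are resolved
  greedily: earliest start wins, ties go to the shorter unit. The
  brute-force oracle in the test suite applies the same published
  tie-break while finding candidates by exhaustion over every
  (start, unit-length) pair, so the scan strategy itself is what the
  equivalence test checks.

The scanner is vectorized: for each k it computes the boolean lag-k
self-equality of the sequence as a numpy array and extracts runs from its
edges, so a megabase scans in tens of milliseconds.

## Motif classes

Repeat units that are cyclic rotations and/or reverse complements of one
another describe the same repeat read in a different frame or from the
opposite strand and are treated as one class. A class is
`rotations(u) ∪ rotations(revcomp(u))` (at most 2k members) and is named
by its lexicographically smallest member, which makes labels deterministic
and sortable. Published tables often use other representatives (CT for the
AG class, TAT for the AAT class); reporters therefore also carry the most
frequent observed spelling (`observed_label`) so tables can be rendered
either way. The class counts for k = 1…6 are 2, 4, 10, 33, 102, 350,
verified in tests against an independent union-find over all 4^k strings.

## Compound SSRs

Two SSRs on one sequence whose gap (next.start − previous.end) is strictly
below 100 bp are chained, transitively, into a compound SSR. The boundary
is strict: a 99 bp gap merges, a 100 bp gap does not. Compound members
remain individual records in all count statistics — per-unit-length counts
must sum to the total — and compounds are reported separately in the
MISA-style table (type `c`).

## Summary statistics

For a sequence set of length L bp (N bases included — published surveys
divide by whole-genome length) with C SSRs of summed length S:
abundance = C/(L/10⁶) SSRs/Mb; SSR content = 100·S/L %. "Frequency" has
two distinct senses in the literature and is kept apart explicitly:
`frequency_of_total_pct` (a unit-length category's share of all SSRs) and
`frequency_within_unit_pct` (a motif class's share of its unit-length
category). All computation is at full precision; display rounding is
half-up to 2 decimals (`round_half_up`), which reproduces published
derived columns exactly. Half-up versus half-even cannot be distinguished
from most printed values; half-up is this package's choice. When a
published table lists only the top classes, `motif_class_summary_from_counts`
takes the full unit-length totals as an explicit denominator override.

## Region categories

From gene → mRNA → exon/CDS GFF3 (parsed with gffutils; 1-based inclusive
converted to 0-based half-open internally):

* gene = merged gene spans; intergenic = per-sequence complement;
* exon = union of exon intervals across transcripts; intron = per
  transcript (span − exons), unioned — a base is exonic if exonic in any
  transcript and intronic if intronic in any;
* CDS = union of CDS intervals; UTR = exon − CDS per coding transcript,
  unioned (non-coding transcripts contribute no UTR);
* category lengths use merged intervals, so overlapping transcripts are
  not double-counted.

Categories are nested by construction, so SSR assignment is deliberately
non-exclusive: an SSR is counted in every category it overlaps by ≥ 1 bp.
Densities are count per Mb of the category's merged length.

## Gene-element partition and relative positions

Only genes whose representative transcript (the one with the most exons,
ties by id) has ≥ 7 exons — hence ≥ 6 introns — are profiled; with fewer
exons the 13 elements are not all populated. Ordered 5′→3′ (strand-aware),
the elements are: upstream500, exon1, intron1, exon2, intron2,
middle-left exons, pooled middle introns, middle-right exons, last-second
intron, last-second exon, last intron, last exon, downstream500. The
middle exons are split at the midpoint of their ordered list with an odd
exon going to the left half — no published rule exists for this split, so
a deterministic, strand-symmetric one was chosen. Flanks are the 500 bp
immediately beyond the gene span, clipped at sequence ends.

An SSR fully inside an element interval gets
value = offset₅′ / (element length − SSR length), clamped to [0, 1], with
the degenerate case (SSR fills the element) set to 0.5 — the only
strand-symmetric choice. Bins are left-open/right-closed tenths P0.1…P1.0
with value 0 in P0.1. An SSR straddling element boundaries is counted
once, in the element holding the greater share (ties to the 5′ element),
without a bin, so per-element bin counts sum to the contained-SSR count.

## Synthetic data

The generator emulates what the real inputs provide — multi-sequence
assemblies with N runs, gene models with ≥ 7 exons on both strands, and
planted perfect SSRs with known classes, counts, region categories,
element labels and relative positions — while making recovery exactly
checkable:

* **Background sterility.** Uniform-random ACGT is scanned with the miner;
  any detected run is broken by one mid-run substitution and the sequence
  re-checked to a fixed point. At uniform base composition a megabase
  contains only a handful of threshold-passing runs, so this converges in
  a few rounds.
* **Planted maximality.** Each planted repeat's flanking bases are chosen
  to differ from the unit's terminal bases, so the mined record's
  coordinates equal the planted coordinates, not merely overlap them.
* **Separation.** Planted blocks are kept ≥ 120 bp apart (beyond the
  100 bp compound cutoff) unless an explicit chain with stated gaps is
  requested; chains are how compound fixtures are built.
* **Junction cleanup.** Writing a repeat into background can in principle
  create an incidental SSR across the junction; after planting, the
  sequence is re-mined and any record not in the truth set is broken by a
  substitution outside planted spans, to a fixed point.
* **Truth bookkeeping.** Region categories and element labels/bins in the
  truth table are computed from the generator's own layout arithmetic,
  not by running the annotation modules, so end-to-end tests compare two
  independently derived answers (the relative-position formula itself is
  definitional and shared).

The standard benchmark (`benchmark_config`) is the package's study-scale
fixture: two sequences totalling ~1.08 Mb, eleven genes (nine with 7–11
exons on both strands, plus a 3-exon and a 6-exon gene that sit below the
profiling cutoff), N runs of 400 and 250 bp, and ~231 planted SSRs
covering all six unit lengths, every region category, all 13 element
labels, pinned relative positions in every tenth bin, and one explicit
two-member chain 50 bp apart. The scale was chosen so the full
mine → regions → profile → verify cycle runs in a couple of seconds while
still exercising every code path at genome-like geometry; what it does
*not* emulate is biological base composition, isochores, transposon-
associated SSR clustering, or realistic SSR length distributions — passing
tests demonstrate algorithmic correctness, not biological realism of any
particular abundance value.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; GFF3 and
  MISA-style outputs convert to 1-based inclusive at the boundary.
* Empty SSR lists give zero counts and 0% content; frequencies of an empty
  total are reported as 0 rather than NaN.
* A zero-length genome denominator raises.
* Relative positions are clamped to [0, 1] before binning; bin edges are
  computed with a 1e-9 rounding guard so exact tenths land in their own
  bin.
* Statistics are invariant to input order (sorted aggregation throughout);
  pipeline outputs are a pure function of (inputs, config), verified by
  digest comparison.

## Known limitations

* Imperfect or interrupted repeats beyond compound merging are out of
  scope, as are unit lengths above 6 and IUPAC ambiguity motifs.
* Genes without mRNA/transcript children (e.g. pseudogene-only records)
  contribute their span to the gene category but nothing to
  exon/intron/CDS/UTR.
* UTR is defined only for coding transcripts; transcripts lacking CDS
  annotation contribute no UTR.
* Region-wise results on real annotation depend on the annotation's
  transcript completeness; the union-across-transcripts rule is
  deliberately simple and order-independent rather than
  isoform-resolved.
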
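# Methods

## Problem setting and overall procedure

The package compares peak sets called from epigenomic profiling experiments
that target the same transcription factor on the same genome build. Because
no experiment can be assumed correct, the comparison criterion is motif
content rather than agreement with a designated reference dataset. For each
non-reference peak file a pairwise comparison against the reference file is
run: the two peak sets are split into four groups by the any-overlap
criterion (a peak is *common* iff it shares ≥ 1 bp with any peak of the
other set, under 0-based half-open coordinates), and each group is scored
independently. Both sides of the common set are kept separately — they are
different peak calls over the same loci, and the four-way split is what the
cross heatmaps (below) are defined on.

Peaks are never merged before segregation; duplicate or nested peaks within
one file are kept as-is, and strand is ignored. The overlap test has no
reciprocal-fraction option in this version.

## Peak dialects and summits

MACS narrowPeak carries an explicit summit (start + column-10 offset; an
offset of −1 falls back to the floored interval midpoint). SEACR defines no
summit, so the floored midpoint of its column-6 max-signal region serves as
the summit proxy (interval midpoint when that column does not parse). This
proxy is a package decision — the max-signal region is the closest analogue
to a highest-pileup position — and SEACR-based summit-to-motif results
should be read with that in mind.

## Motif model and scanning

Motifs are position frequency matrices (counts, rows A,C,G,T). The scanning
matrix is the log-odds transform in bits,

    W[b,j] = log2( (n[b,j] + c·p[b]) / (N[j] + c) / p[b] ),

with pseudocount `c` (default 0.1) distributed proportionally to the
background `p`. The background is the 0-order base composition of the
scanned sequence set, A/T and C/G symmetrized, falling back to uniform for
empty input; symmetrization makes one null model exact for both strands.

Occurrence p-values are exact: the matrix is discretized to integer units
(default 1000 per bit — fine enough that rounding is far below any decision
threshold, small enough that the dense convolution table stays tiny) and the
null PMF of the score of a random background w-mer is computed by
position-wise convolution. A window's p-value is the null tail mass at its
integer score; windows containing N are skipped; both strands are scored
against the same null, which makes scanning commute exactly with reverse
complementation of the input. The default occurrence threshold is p ≤ 1e-4.
Tests pin the rounding by comparing the DP against exhaustive enumeration of
all 4^w w-mers for small widths.

Summit-to-motif distance is `summit − occurrence centre` with centre
`start + floor(w/2)`; among several in-peak occurrences the *nearest* one is
used (ties to the leftmost) — the quantity is a distance statistic, so
nearest-occurrence semantics were chosen over best-scoring-occurrence.
Peaks with no occurrence are excluded from the distance statistics and
reported as a separate count; a sentinel value would distort the mean. The
optional bootstrap CI is the 2.5/97.5 percentile interval of the mean
absolute distance over resamples with replacement at the original n
(default 2000 resamples, explicit seed).

## Known-motif enrichment and FRiP

A peak counts as enriched for a motif iff its sequence contains ≥ 1
significant occurrence on either strand (ZOOPS-style presence). Group
results are counts and percentages; rank-based enrichment statistics are
deliberately not reproduced, since the report reasons about per-peak counts.
As an addition labelled as such in the report, the unique-vs-common contrast
within each experiment side is quantified by a two-sided Fisher exact test
on the 2×2 enriched/not table (p = 1 by convention for zero-margin tables).

FRiP counts a read as in-peak iff it overlaps any peak by ≥ 1 bp, each read
at most once. Any-overlap was chosen over midpoint containment as the
simplest defensible convention; it is pinned by tests.

Overlap queries (segregation and FRiP) run against merged per-chromosome
interval unions with binary search, which is exactly equivalent to
any-overlap against the unmerged set; brute-force O(n·m) oracles in the test
suite verify the equivalence.

## De-novo discovery

The discoverer is a k-mer-seeded ZOOPS pipeline, equivalent in role (not in
algorithm) to suffix-tree-based discovery tools:

1. **Control set** — a per-sequence dinucleotide-preserving shuffle
   (Euler-path / Altschul–Erikson), preserving each sequence's mono- and
   dinucleotide multisets exactly; deterministic given the seed.
2. **Seeding** — for k = 6..10, every k-mer (merged with its reverse
   complement) is counted by per-sequence presence in input vs control and
   ranked by one-sided Fisher exact p (hypergeometric tail). K-mers no more
   frequent in the input than in the control are assigned p = 1 — they carry
   no enrichment evidence and must not seed. Ties break lexicographically.
3. **Refinement** — the best seed is expanded by 2 flanking columns per
   side, initialized from all exact seed matches, and refined by 3 ZOOPS
   iterations: take each sequence's best-scoring window above the null
   median score, rebuild the PFM from the aligned sites. Fixed iteration
   count keeps the procedure deterministic and cheap; recovery tests (PCC
   ≥ 0.8 against the generating PFM under 80 % planting) pin the defaults.
4. **Filtering and masking** — motifs whose consensus contains a run of
   `filter_n` identical letters (default 6) are discarded as low-complexity.
   Accepted or not, a motif's sites are masked with N before the next round
   so each round finds something new. Rounds stop at `count` motifs
   (default 3 per group) or when no seed reaches p < 0.05.

Groups with fewer than 5 sequences are skipped (too few for a presence
statistic).

## Motif similarity

Motif-motif similarity is the maximum Pearson correlation of the flattened
4×overlap frequency submatrices over all ungapped offsets with ≥ 4 aligned
columns and both strands; ties prefer smaller |offset|, then the + strand.
Correlation is computed on column frequencies (not counts, not IC-weighted
columns); a constant block is defined to have correlation 0. Ranking uses
raw PCC with no p-value machinery. The four heatmaps of a comparison are
oriented as common = mA×mB, unique = mC×mD, cross A = mC×mB, cross B =
mD×mA, where mA/mB/mC/mD index motifs discovered in common-reference,
common-comparison, unique-reference and unique-comparison peaks. The
closest-known-motif table is the PCC argmax over the supplied database
(ties to the earlier entry; entries narrower than the minimum overlap are
skipped).

## Synthetic data generator

The generator emulates the minimal structure the metrics respond to: a
single-chromosome i.i.d. genome with controllable GC; non-overlapping
fixed-width peaks on a slot grid; one motif instance per planted peak,
letters sampled column-wise from the PFM (so discovery recovery is a
statistical test, not string matching), centred at the summit plus rounded
Gaussian jitter and planted on a random strand; reads placed to hit a FRiP
target exactly; and two-experiment scenarios in which exactly
round(f·n) reference peaks overlap a shifted comparison copy. Defaults:
50 peaks of 200 bp per experiment, planting fraction 0.8, jitter sd 0,
~17-bit 12-bp planted motif, 1000 reads of 50 bp, FRiP 0.3 — sizes at which
every pipeline stage is exercised in seconds while leaving headroom for the
statistical assertions.

What it does **not** emulate: fragment-length/pileup structure, duplicate
reads, multiple chromosomes by default, repeat families, GC-biased peak
placement, or peak-width variability. Passing tests therefore demonstrate
correctness of the computations and recoverability under clean conditions,
not performance on real libraries.

In two-experiment scenarios both experiments plant into one genome; with
large jitter an instance planted for one experiment can in principle
overwrite part of an overlapping instance of the other. At the default
jitter (0) and the shift of one-third peak width this cannot happen.

## Degenerate inputs and numerical conventions

Empty peak groups yield zero counts/percentages rather than errors; empty
similarity matrices keep labelled zero dimensions; sequences shorter than
the motif yield no occurrences; a zero-margin Fisher table gives p = 1;
a PFM with zero cells requires a positive pseudocount. Medians of
even-length width vectors average the central pair. All randomness flows
through explicit integer seeds; results are bit-identical across repeat
runs and across worker counts (per-comparison work is self-contained and
seeded independently of scheduling).

## Known limitations

* TRANSFAC motif input, bigWig/bedGraph tracks and broadPeak are not
  supported; BAM reads are an optional adapter behind the BED contract.
* Discovery is a role-equivalent stand-in for suffix-tree discoverers:
  seed statistics and ZOOPS counts match the k-mer formulation, but p-value
  refinement on hold-out sequences and Markov models above order 1 are out
  of scope.
* The Fisher unique-vs-common contrast is an addition of this package, not
  part of the original count/percentage reporting; the report labels it.
* Genome "build names" are not resolved remotely; a FASTA path must be
  supplied. Nothing is ever downloaded.
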
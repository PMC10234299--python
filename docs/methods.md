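# Methods

This note records what each stage computes, the defaults and why, what the
synthetic data does and does not emulate, and the numerical choices made
where the procedure left room.

## Alignment model and filtering

The unit of input is one PAF file per haploid assembly aligned to a single
complete reference. Sample and haplotype identity come from file
provenance (CLI flags), never from contig-name parsing, because naming
conventions differ between assembly producers. Records are kept when
mapping quality ≥ `min_mapq` (10), reference-axis width ≥ `min_aln_width`
(1 kbp) and total contig size ≥ `min_ctg_size` (100 kbp). The width filter
is applied on the *target* (reference) axis: all downstream gap logic lives
in reference coordinates, and for near-colinear contig alignments the two
axes differ negligibly. Secondary alignments are assumed absent (the
expected aligner invocation uses `--secondary=no`); a `tp:A:S` tag drops
the record with a warning. No CIGAR or `cs` parsing is done — no stage
needs base-level detail.

All thresholds live in one immutable `Thresholds` object; every output file
echoes it as a `## thresholds:` header that round-trips to an identical
object, so a run is reproducible from its outputs.

## Contig ends, pieces and gaps

Two end definitions serve different purposes. *Simple ends* (first/last
alignment with ≥ 25 kbp aligned, one point per contig side) are the unit of
enrichment accounting: cheap, one pair per contig. *End alignments*
(terminal alignments ≥ 50 kbp) delimit gap regions and must therefore be
consistent with the contig's length: if the reference span between a
contig's terminal alignments exceeds its length by more than
`overextension_frac` (5%), the contig cannot be treated as one colinear
piece. It is then partitioned into the minimal number of pieces such that
each piece's span obeys the 5% rule, cutting at the largest
reference-coordinate jumps between query-adjacent alignments —
the parsimonious choice, since large target jumps are exactly what inflates
the span. Minimality and feasibility of the greedy largest-jump choice are
verified against exhaustive partition search in the tests; when the greedy
cut set is infeasible the implementation falls back to exact subset search
(contigs of ≤ 16 alignments; beyond that, greedy only). Cross-chromosome
contigs are always split at chromosome boundaries first — a span across
chromosomes is undefined.

Ends are reported in reference orientation (left = smaller coordinate) so
that gap construction is uniform for reverse-oriented contigs. Gaps are
emitted per haplotype, per chromosome, between the running rightmost piece
end and the next piece's left end; overlapping or abutting pieces emit
nothing (zero-length gaps are suppressed), and nested pieces (embedded
contigs) cannot create spurious gaps because the running maximum is used
rather than naive pairwise adjacency.

## End annotation and enrichment

Labels are nonredundant: exactly one per end, highest priority within
`proximity` (10 kbp) wins. Default priority — chromosome end (within
100 kbp of a reference chromosome terminus; the implicit top rank), the
SD+GA/TC composite, SD, satellite, GA/TC, AT, Poisson end, other — is
configurable since the canonical order is a presentation choice; the
chromosome-end-beats-SD rule and the separate accounting of SD vs SD+GA/TC
are fixed points. "Chromosome end" is interpreted as proximity to a
*reference* chromosome terminus. A *Poisson end* is an end with no end
from any other haplotype within 10 kbp on the same chromosome
(nonrecurrent, presumed random; the clustering distance reuses the global
proximity as no separate value is established). Recurrence counts distinct
haplotypes, so one diploid sample can contribute at most two.

Permutation enrichment deliberately differs from labelling: an end may
count toward every track it is near, and the null places the same number
of ends uniformly over the concatenated chromosome lengths with no masking
(an exclusion BED can be supplied). Implementation note: a permutation
reduces to membership of uniform draws in the proximity-padded, merged
track intervals, so 10,000 permutations are a single vectorized
`searchsorted`. Fold is observed over the median of the permuted counts;
when that median is 0 the fold is undefined and reported as the observed
count with a flag. The empirical p-value uses the add-one form
(1 + #{random ≥ observed}) / (1 + N), so p ∈ (0, 1]. Calibration (fold → 1,
p uniform by Kolmogorov–Smirnov under the null; planted case matching the
closed-form binomial expectation) is asserted in the acceptance tests.

## Discontinuities

For query-adjacent alignments of one contig on one chromosome, the target
gap is measured between the two alignments' reference intervals after
ordering them by reference coordinate (this makes the computation valid
for reverse-oriented contigs), and the query gap is the unaligned contig
bases between them. Classification: contraction when target gap > query
gap, expansion when smaller, event size the absolute difference. Choices
for the cases the definitions leave open: a pair with target gap 0 and
query gap > 0 is an expansion (point insertion); both zero emits nothing;
equal nonzero gaps are recorded as "neutral" and excluded from recurrence;
overlapping query intervals are skipped with a warning (split-alignment
artifacts); overlapping target intervals are not discontinuities (they are
the multicoverage signature). Strand-switch pairs are evaluated and
labelled rather than suppressed — an inversion breakpoint legitimately
presents as two such pairs — and maximal reverse-strand runs inside
otherwise-forward contigs are additionally reported as misoriented
(inverted) segments. Target gaps ≥ 1 Mbp are piece boundaries, not
discontinuities.

## Multicoverage and copy number

Multicoverage regions come from an event sweep (depth changes only at
interval boundaries); equality with a per-base depth oracle is asserted on
randomized instances. The embedded flag is strict containment of one
contributing contig's whole per-chromosome aligned span inside another's.

Copy-number conversion is intentionally reduced to its classification
core: CN = diploid × depth / mean(control-window depth), with an optional
per-GC-decile rescaling when window GC is provided. The full
short-read-remapping depth estimator is out of scope; the four-way call is
the contribution here. Regions are classified on region-mean CN rounded
half-up to integers (regions, not windows, are the unit; half-up is the
conventional tie-break), delta = sample − reference: noCN when sample
CN = 2 *or* delta = 0 (the disjunction read literally); CNV when
delta ≥ +1 and sample CN < 10; more10CN when delta ≥ +1 and sample
CN > 10; sample CN exactly 10 with an increase falls through to "none"
(the strict inequalities leave it unassigned; we do not guess); regions
with no windows are "uncallable", distinct from "none".

The LOH screen formalizes a qualitative artifact signature: a contig is
flagged when its het density in the overlap is below 10% of the
assembly-wide median *and* it differs from the opposite-haplotype contig
at under 10% of the expected het rate. Both 10% thresholds are this
package's own operating points and are configurable.

## Low-complexity tracts and windows

Tract sizing: overlapping occurrences of TA, TC and GA are counted in
non-overlapping 100-bp bins (occurrences straddling a bin boundary count
in neither bin — the simplest deterministic rule — and the straddle count
is recorded); Z-scores are computed per analyzed sequence, not
genome-wide; bins with Z ≥ 1.96 are enriched; tract size is the enriched
run length × 100. Zero variance (e.g. a pure homopolymer or pure tract
with nothing else) yields no calls and is flagged degenerate. Sizing error
is bounded by bin phase: ±2 bins (±200 bp) for planted pure tracts of
300–6,500 bp, asserted over all 100 phases.

Window flagging: "GA/TC content" of a 1-kbp window is the fraction of
bases covered by GA or TC dinucleotide occurrences — 1.0 on a pure tract,
≈ 0.23 on random sequence, so the 0.80 threshold separates cleanly. The
window slides in 100-bp steps (step size is a free choice; merging of
overlapping flagged windows makes results step-insensitive for tracts
≥ 1 kbp). The AT detector is the same machinery with the AT/TA pair and
the same threshold — no separate AT threshold is established, so the
GA/TC rule is mirrored and left configurable.

## Validation

Gap spanning requires a single read alignment to strictly contain the gap
(mapq ≥ 10); ≥ 10 such reads mark the gap closable. An any-overlap mode
exists behind a flag but containment is the default reading of "spanned".
Phasing concordance cuts the genome into 1-Mbp blocks, assigns each block
to the truth haplotype matching the majority of the test haplotype's
alleles at shared sites (ties and empty blocks unassigned; terminal
sub-1-Mbp blocks evaluated if they contain any informative site; missing
positions ignored, no imputation), and reports per-chromosome and overall
concordance over assigned blocks plus maximal runs of discordant blocks —
the large-scale switch-error signature. Swapping truth haplotype labels
flips every assignment and leaves concordance invariant (tested).

## Synthetic data: what it does and does not show

The generator emulates the *coordinate structure* of a fragmented diploid
assembly: a uniform-random ACGT background with planted SD pairs at a
controlled identity (per-base binomial divergence), tandem satellite
arrays, pure dinucleotide tracts and gene intervals; and per haplotype the
six event kinds (gap, inversion, expansion, contraction, embedded contig,
tandem copy gain). The truth PAF is constructed analytically — one row per
maximal colinear segment, mapq 60 (an explicit low-mapq injection option
exists for filter testing) — which removes aligner nondeterminism from the
test surface; the contig FASTA is also written for anyone who wants to run
a real aligner instead. Everything is driven by `numpy.random.default_rng`
with an explicit seed recorded in output headers; identical inputs give
byte-identical outputs.

The canonical demo is one 10-Mbp chromosome (≈ diploid 2 × 10 Mbp) with
12 gaps, 6 contractions, 6 expansions, 2 inversions and 3 embedded
contigs, events ≥ 250 kbp apart so every flanking piece stays
independently alignable, gap sizes 20–100 kbp and event sizes 5–50 kbp —
small enough that the full pipeline runs in seconds, large enough that
every threshold (25/50-kbp ends, 100-kbp contigs) is exercised with
margin.

What passing on synthetic data does *not* show: no read-level error
models (no HiFi coverage dropout, no ONT simulation), no aligner ambiguity
in repeats (real minimap2 output near long, highly identical SDs and
satellite arrays is far noisier than the analytic truth), no satellite
higher-order structure, and uniform background composition. Exact 100%
recovery is therefore a statement about the interval logic, not about
expected performance on real alignments.

## Problem sizes

Default test and acceptance runs use the 10-Mbp demo genome, 200
randomized oracle instances, 200 enrichment replicates at 1,000
permutations (10,000 for the planted case), and 100-kbp backgrounds for
tract sizing — sizes chosen so the whole suite completes in well under a
minute on one CPU while keeping every statistical check adequately
powered.

## Known limitations

Haplotype attribution of collapsed contigs is not attempted; recurrence
analysis treats haplotypes, not samples, as the unit; the copy-number
estimator is a control-region scaler, not a full GC-corrected remapping
pipeline; inversion adjudication beyond split-alignment strand runs
(e.g. dot-plot curation, strand-aware sequencing evidence) is out of
scope.
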
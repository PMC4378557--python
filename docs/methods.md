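# Methods

## Coordinate and sequence conventions

All in-memory coordinates are 0-based half-open; report files use 1-based
inclusive coordinates (window strings render as e.g.
`chr11:3,180,001-3,200,000`). The converters live in `sbkit.io` and nowhere
else. A TA site is identified by the plus-strand coordinate of its T; TA is
its own reverse complement, so the TA index is strandless. Strand on
insertion records denotes ITR orientation, not TA strand. Motif scanning
accepts the IUPAC codes A, C, G, T, N, W; an N base in the genome never
matches anything (including N), so assembly gaps cannot produce motif hits.
When exon and intron annotation overlap, exon wins: the consequence of a
footprint is most severe in coding sequence, and classification follows that
emphasis.

## Footprint model and calling

SB excision leaves three ITR-derived bases between the duplicated TAs of the
integration site, so a donor locus that read `TA` before integration reads
`TACAGTA` or `TACTGTA` after excision — a net 5-bp gain. The simulator
implements integration (`prefix + TA + transposon + TA + suffix`) and
excision (replacement of the occupied locus by a footprint 7-mer) exactly,
and chooses between the two consensus variants uniformly, as there is no
evidence of asymmetry between them.

The caller applies four filters in order: (1) subtract sites present in the
matched tissue normal (endogenous TACWGTA loci); (2) remove the sample's
known clonally expanded insertion sites (surviving ITR/genome junctions carry
the same restriction site); (3) remove sites recurring in more than one tumor
— footprints are assumed private to a sample, and a recurrent site is dropped
from *all* samples, not merely deduplicated; (4) require at least one read on
each strand, which guarantees an intact 7-mer across the locus. Steps 1–3
are set subtractions and commute; the chosen order is the documented one and
is asserted by permutation tests.

Confidence tiering compares a candidate's total depth with the depths of
simultaneously sequenced clonally expanded insertion loci. The published
procedure states the comparison but not the cutoff; this implementation uses
a percentile threshold (default: the 25th percentile of the clonal reference
depths, linear interpolation) and exposes it as a parameter. The
true-footprint estimate is `ceil(n_high · r_high + n_low · r_low)` with
tier-specific validation rates pooled across samples; the ceiling reflects
that a partially validated tier still implies at least the next whole
footprint, and it reproduces the published per-tumor estimates exactly.

The exon-enrichment test uses the one-sample proportion z statistic,
`z = (k/n − p0) / sqrt(p0 (1 − p0) / n)`, two-tailed; the two-proportion test
against a genome-wide TA census is this form in the limit of an infinite
reference sample. `p0` defaults to the exonic TA fraction computed from the
supplied annotation rather than a hard-coded constant. A warning is issued
when `n·p0 < 5`.

## Clonality and replicate FDR

Read counts are normalized to percent-of-maximum within a declared site
class: spike-in standards are normalized to the most abundant standard,
genomic sites to the most abundant genomic site, so that standards do not
perturb genomic percentages. Abundance bins are half-open `(lo, hi]` with
default edges 0, 1, 5, 12.5, 50, 100: only the 5% boundary is externally
meaningful (the zero-FDR threshold); 12.5 and 50 follow the spike-in tiers,
and the 1% edge separates the singleton-dominated tail. All edges are
configurable.

The FDR estimator rotates over replicates: each replicate in turn is the
test set; sites present in *both* remaining replicates form the true-positive
set; a test-set site outside it is a false positive. Presence means raw
detection (count ≥ 1), not a normalized floor — the simplest reading of
presence/absence. Per-bin rates are averaged over rotations, skipping
rotations in which a bin is empty; a bin empty in every rotation reports NaN
rather than an arbitrary zero.

Ligation points are modeled as distinct shear positions among a site's
fragments (uniform over a configurable shear span, 300 bp default), hence
always bounded by the read count and saturating at high depth — which is why
grouping by ligation points separates abundance tiers less cleanly than
read counts, a behavior the tests assert.

## Detection-bias scan

Windows are fixed-width (20 kb default), non-overlapping, tiled from zero
per sequence with the final partial window retained. The observed statistic
is the number of distinct insertion sites, never reads: within a sample,
multiple records at one TA (both ITR orientations) collapse to one; the same
TA in different samples counts once per sample, and samples are pooled
before fitting.

PRIM is a Poisson GLM (log link) of per-window distinct-site counts on
`log(TA count)` with a chromosome factor, fitted by `statsmodels`; the
factor is dropped automatically for single-sequence genomes, and windows
with zero TA sites are excluded from fitting and from the Bonferroni family
(they are reported with p = 1). The per-window p-value is the exact Poisson
upper tail at the fitted mean rather than a regression-based test: it is
reproducible, conservative at small means, and identical in spirit. The
family-wise α is a parameter (0.05 default) since the published threshold
style ("p < 1.0E-7" after correction) does not pin down α and N separately.

Under a dominant planted hotspot the GLM mean itself is inflated — the score
equation forces fitted means to sum to the observed total — so hotspot
detection is asserted by rank (the planted window is top-ranked), and type-I
control is asserted under the uniform null.

## Mappability

For each TA site and strand, mock reads anchored at the TA (first two bases
`TA`; the anchor offset is configurable) are generated at lengths 10–65 bp
in 5-bp steps, skipping reads that would cross a sequence end. The built-in
aligner is an exhaustive both-strand Hamming scan reporting every placement
with at most 2 mismatches, scored match +1 / mismatch −1 so a perfect
L-mer scores L; this scoring makes the "score > 10" accuracy rule meaningful
across the 10–65 bp grid (a perfect 10-mer scores exactly 10 and fails, so
the smallest attainable minimum is 15). External aligners with their own
score scales can be plugged in through the `AlignerAdapter` protocol; their
scores pass through unchanged, which shifts the smallest qualifying length
accordingly.

A length qualifies when the originating locus is hit with score > 10 and no
*other* locus is hit with fewer than 2 mismatches — i.e. uniqueness requires
every alternative placement to carry at least 2 mismatches. The source
phrasing of this rule is grammatically ambiguous; this reading (a
near-perfect alternative makes the read ambiguous) matches the evident
intent, and both the mismatch limit and its direction are parameters.
Monotonicity of qualification in read length is not assumed: each grid
length is evaluated independently and the minimum over the grid is reported,
with a sentinel for sites failing at every length. Read filtering then
retains an experimental read iff its length reaches the minimum at its
(site, strand).

## Simulator defaults (the study conditions)

* Spike-in / clonal tiers: 1.0, 0.5, 0.125 copies per genome — ten standards
  split 4/3/3 across tiers, each with physically linked left- and right-ITR
  templates at two loci.
* Clonal tumors: ten clonally expanded sites across the three tiers plus 200
  background passenger sites with clonality log-uniform in [2×10⁻⁵, 6×10⁻⁴],
  low enough at default depth to drop in and out of replicate libraries.
* Replicates: three libraries per tumor at 30,000 reads each — a scaled-down
  library depth chosen so that tier separation and background drop-out both
  occur, the regime the clonality analysis addresses.
* Count noise: Poisson by default; negative binomial with
  `var = μ + d·μ²` when dispersion `d > 0`.
* Local hopping: 6 Mb window, p(local) = 0.85, both configurable; the
  per-event remobilization probability is a free parameter with no default
  asserted as biological truth.
* Toy genomes: i.i.d. bases within 20-kb blocks whose GC content is drawn
  uniformly from a configurable range (0.35–0.55 default; 0.3–0.7 in the
  bias-scan tests). This isochore-like heterogeneity makes TA density vary
  between windows; without it the log-TA covariate is nearly constant and
  the regression weakly identified.

What the simulator does *not* model: base-call errors and quality scores,
PCR-cycle-explicit amplification bias (shearing-based LM-PCR showed no
size-dependent bias between paired templates), chromatin or transcription
effects on target choice, and real repeat families (duplications are
constructed explicitly where needed). Passing tests therefore demonstrate
correctness of the algorithms under these idealized generative conditions,
not performance on real libraries.

## Problem sizes and numerical choices

Tests and examples run on genomes of 10 kb–1.2 Mb with 2,000–50,000
simulated sites; these sizes were chosen so every statistical property
(coefficient recovery within ±0.1 at 50,000 sites, type-I control over 20
seeded runs, hotspot ranking, tier separation) is computed from data the
suite generates itself. Genome-scale quantities from real screens (hundreds
of thousands of loci, window counts over a full mouse genome) are out of
scope at desk scale and are deliberately not asserted.

Percentile thresholds use linear interpolation (`numpy.percentile` default).
Poisson tails are computed by `scipy.stats.poisson.sf`, never by normal
approximation. All simulation randomness flows through
`numpy.random.default_rng(seed)`; every stochastic API takes an explicit
seed and is exactly reproducible given (seed, parameters). Ties in aligner
hit ordering are broken by (score, chrom, position, strand) for determinism.

## Known limitations

* The built-in aligner is exhaustive and intended for toy genomes (≤ a few
  hundred kb); genome-scale mappability requires an external aligner behind
  the adapter protocol, whose score scale then defines the accuracy rule.
* The leave-one-out FDR treats replicate libraries as exchangeable; batch
  effects between replicates would inflate it.
* The exon-enrichment test's reference proportion depends entirely on the
  supplied annotation; with a sparse toy annotation the test is
  underpowered and the small-expected-count warning will fire.
* `ta_composition` classifies sites one at a time through the interval
  trees; it is O(TA count · log intervals) and meant for toy genomes.
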
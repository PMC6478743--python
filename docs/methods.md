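# Methods

`mmsv` implements the downstream computations of a myeloma whole-genome
structural-variant analysis: post-caller translocation QC and clonality
estimation, translocation hotspot discovery, copy-number cytogenetic
classification (including hyperdiploidy), translocation–amplification
proximity, survival analysis with permutation significance, ROSE-style
super-enhancer calling, and immunoglobulin expression typing. It operates
on caller output (BEDPE/VCF breakends, SEG-style segments, BED
annotations), never on raw reads. A seeded synthetic-cohort generator
provides the end-to-end test bed; this note records the models, the
defaults, and the design decisions that were genuinely open.

## Coordinates

Internally everything is 0-based half-open (BED convention). VCF breakends
and SEG tables are 1-based and are converted exactly once, at the I/O
boundary. Chromosome names are taken verbatim; readers accept an optional
alias map.

## Translocation QC

Three filters are applied to candidate inter-chromosomal calls:

* **Flank homology.** 1 kb of sequence on either side of each breakpoint
  end is extracted (truncated at chromosome ends, never wrapped). The
  filter fires when any 100 bp window of a side-A flank matches a 100 bp
  window of a side-B flank at ≥ 80% ungapped identity, with both strands
  of side B considered. The metric is a maximum over all window-offset
  pairs — an O(L²) scan organised by diagonal so each diagonal reduces to
  a vectorised sliding-window sum. Ungapped identity is the minimal model
  consistent with a per-window identity threshold; gapped/BLAST-style local
  alignment would only merge windows the scan already finds. Tests compare
  the scan against an independent one-hot matrix-product oracle over all
  offsets, including constructed pairs with exactly 79/100 and 80/100
  matching positions.
* **Mappability.** The mean per-base mappability over the 2 kb around each
  breakpoint end (1 kb on either side) is computed per end from a
  step-valued track; uncovered bases count as 0. A call is removed when
  either end's mean is strictly below 0.20. Averaging per end (rather than
  pooling both ends) was an open reading; it is the stricter and more
  local interpretation and is configurable.
* **Blacklist.** Membership is overlap of the breakpoint position itself
  (not its flanks) with a user-supplied BED of recurrently artifactual
  regions.

A call is removed iff at least one filter fires; kept and removed calls
partition the input, removal reasons are recorded, and the procedure is
idempotent. Calls whose flanks are shorter than the scan window are kept
and flagged `unevaluable` rather than silently judged.

**VAF.** The variant allele frequency of a translocation is the ratio of
reads spanning the rearranged junction to all reads spanning the
breakpoint. For a clonal heterozygous event in a diploid region this is
~0.5; values near 0.25 indicate sub-clonal events. Zero-coverage calls
keep an absent VAF rather than a 0.

**Breakpoint mechanism classes.** IgH breakpoints are classified as CSR
(within ±2.5 kb of a class-switch region), VD (inside the
variable/diversity segment region), or extragenic, with CSR taking
precedence where the extended windows overlap; the classes are exhaustive.
Location biases are summarised as odds ratios with the Haldane–Anscombe
0.5 correction when a cell is empty, and two-sided Fisher exact p-values.

## Hotspot discovery

A 1 Mb window advanced in 0.5 Mb steps tiles each chromosome from
position 0 (the tiling phase is not observable in practice and 0-anchoring
is reproducible); the final partial window is kept. A window's frequency
is the fraction of cohort samples with ≥ 1 breakpoint end inside it — a
sample with several breakpoints in one window counts once. Windows at or
above the 1% floor are stitched when they overlap; because neighbouring
windows share half their span, a run of consecutive qualifying steps
merges into one region, while two qualifying windows separated by a
sub-threshold step (whose intervals merely abut) remain distinct regions.
Region frequency and median VAF are recomputed over the merged interval.

Recurrent partner pairs count samples with a call joining the 1 Mb
neighbourhoods (inclusive at the radius, measured to the nearest anchor
base) of two anchor loci; when a sample has several such calls, the one
with the highest total read support (ties to the lowest coordinate)
contributes its VAF.

## Copy-number cytogenetics

Copy number arrives as per-sample segments of log2(tumor/normal). Bin
values and region calls use length-weighted means; gain is a mean ≥ +0.2
and loss ≤ −0.2 (both inclusive). The loss threshold is the mirrored
negative of the gain threshold: a non-negative loss cutoff would be
self-contradictory. The cytogenetic panel is supplied as intervals — named
`del(1p)`, `amp(1q)`, `del(13)`, `del(17p)`, plus two `HD` control regions
on each of the eight gain-eligible chromosomes — so the classifier never
depends on cytoband nomenclature. Hyperdiploidy requires concordant gains
of both control regions on at least 4 chromosomes ("at least" reads the
requirement as a minimum; the count is configurable). The rule is monotone:
adding a gain can never lose an HD call. Regions without segment coverage
are called neutral with a warning.

**Boundary proximity.** A boundary is any position where the
gain/neutral/loss state changes between adjacent pieces of the chromosome
partition (uncovered gaps count as neutral, so the edge of a non-neutral
segment is always a boundary). A breakpoint is "proximal" when the nearest
boundary is ≤ 10 kb away (inclusive). An optional `max_segment_span` cap
restricts boundaries to those flanked by a non-neutral segment no longer
than the cap — a focality restriction, off by default because focality has
no principled universal cutoff.

Co-occurrence of binary per-sample annotations uses Fisher's exact test
(hypergeometric) with Benjamini–Hochberg FDR adjustment.

## Survival

Kaplan–Meier estimation and Cox proportional-hazards fits (Efron tie
handling, Wald tests, 95% CIs) are delegated to lifelines. For a count
covariate, the hazard ratio at the maximum observed count is
exp(coef × max), expressing the hazard of carrying the maximum burden.

The **permutation bootstrap** for a binary label shuffles the label across
patients B times (group sizes preserved — the procedure permutes, it does
not case-resample), refits the single-covariate Cox model each time, and
reports p = (1 + #{|log HR_perm| ≥ |log HR_obs|}) / (B + 1). Two-sided on
|log HR| by default (one-sided available), matching its role as a
robustness check on a two-sided Wald test; the +1 correction prevents
p = 0. Degenerate permutations (a group without events, or separation) are
redrawn and counted. The permutation engine is an in-package
single-covariate Newton solver with Efron tie handling, vectorised over
risk sets; it is exact and agrees with lifelines to its convergence
tolerance and with an independent brute-force maximiser to 1e-8, and makes
a B = 1000 bootstrap a sub-second operation. Monotone likelihoods
(separation) raise an explicit error rather than diverging silently.

The **matched downsampling comparison** addresses unequal group sizes
(e.g. asking whether a small group's IMiD benefit differs from a large
group's): the large group is subsampled without replacement to the small
group's size B times, the statistic recomputed each time, and the small
group's observed value placed in the resampled distribution with a
one-sided +1-corrected empirical p.

## Super-enhancer calling

Peaks carrying an occupancy signal (reads per million) are first purged of
promoter overlaps — promoters are the strand-aware 2.5 kb upstream of each
TSS including the TSS base, with no downstream extension (deliberate,
configurable) — then merged transitively whenever the inter-peak gap is
≤ 15 kb (inclusive). Region signal is the sum of component peak signals.
Regions are ranked by signal; both axes of the rank-vs-signal curve are
min-max scaled to the unit square and the cutoff is the point where the
tangent slope equals 1 (equivalently, the minimiser of scaled-signal minus
scaled-rank on the ascending curve). Regions with signal strictly above
the cutoff are super-enhancers. Conventions for degenerate inputs: a flat
curve has no elbow and yields zero supers; a single region is super. Tests
check the tangent cutoff against an independent chord-distance-maximisation
oracle; super/non-super assignment is invariant to positive rescaling of
the signal.

## Immunoglobulin expression typing

The heavy-chain isotype is the argmax over IgH constant-region FPKM,
accepted only at ≥ 5000 FPKM (inclusive); exact ties resolve to the first
constant region in genomic order, with a warning. The light chain is
whichever of the cumulative IgK and IgL (variable + joining + constant)
FPKM is larger, with no minimum threshold by default and ties going to
lambda (arbitrary, warned). Light-chain calls are invariant to uniform
rescaling of a sample; isotype calls are not, because of the absolute
floor — both directions are asserted in tests.

## Synthetic cohort generator

The generator emulates the statistical structure of a newly-diagnosed
myeloma WGS cohort; it does not reproduce patient data. All randomness
derives from a single master seed (separate child streams for events,
genome sequence, and peaks, so the genome can be built lazily without
perturbing the rest), and identical seeds give byte-identical files.

* **Toy genome.** 12 chromosomes: four 6 Mb chromosomes carrying IgH (with
  VD region and six 2 kb switch regions), MYC, IgL, and IgK; eight 5 Mb
  chromosomes eligible for hyperdiploid gain, four of which also carry the
  recurrent partner anchors (CCND1, WHSC1, TXNDC5, MAP3K14). Separating
  the anchored-locus chromosomes from the HD chromosomes mirrors the real
  genome (chromosomes 8, 14, 22, 2 are not among the odd HD chromosomes)
  and keeps whole-chromosome gain boundaries away from the MYC locus.
  Sequence is uniform random ACGT, built on demand.
* **Translocations.** IgH-type clonal events in 41% of samples (partners
  weighted toward CCND1 and WHSC1; breakpoints 75% CSR / 10% VD / 15%
  extragenic); MYC-type sub-clonal events in 23% (partners IgL/IgH/
  TXNDC5/IgK/random at the cohort's printed proportions; IgH-MYC events
  are generated in this branch so a sample carries at most one MYC event);
  additional IgL-other events in 6%, putting t(IgL) at ~10% with ~41% of
  it IgL-MYC. Clonal VAF is Beta with mean 0.48, sub-clonal mean 0.26;
  read support is binomial at Poisson(40) depth, so reported VAFs carry
  realistic sampling noise.
* **Copy number.** 85% of MYC-type events get a focal amplification
  (log2 +0.5, 100–600 kb) whose nearest boundary sits at a uniform 0–10 kb
  from the MYC-side breakpoint; the rest get none. 68% of t(IgL) samples
  get an IgL 3' enhancer amplification. Hyperdiploid samples (probability
  0.78 given IgL-MYC, 0.15 given a clonal IgH event, 0.60 otherwise —
  overall ≈ half) gain 4–8 whole HD chromosomes at log2 0.45, the trisomy
  ratio at the high tumor purity of CD138-sorted myeloma; non-HD samples
  may carry 0–3 sporadic gains, below the HD threshold. The focal panel
  events (amp(1q) 30%, del(13) 35%, del(1p) 20%, del(17p) 10%) follow
  their approximate population frequencies. Segments partition each
  chromosome, with N(0, 0.05) noise per segment and Poisson(2) passenger
  cut points per chromosome.
* **Artifacts.** 10% of the genuine call count is added as planted
  artifacts: homologous-flank pairs (a 160 bp copy with 12 planted
  mismatches, ≥ 88% identity in every window), blacklist-resident
  breakpoints, and breakpoints centred in low-mappability zones — one
  class per artifact, recorded in the truth file.
* **Survival.** Exponential event times with log-linear effects: HR 2.0
  for t(IgL), HR 0.6 for IMiD exposure *only in non-t(IgL) patients* (the
  planted interaction), HR 1.4 for amp(1q), 0.8 for HD, 1.02 per
  structural variant; baseline hazard 0.25/year. Censoring is independent
  exponential with the rate chosen per subject so that exactly 30% of
  observations are censored in expectation.
* **Expression and peaks.** Isotype and light-chain (2:1 kappa:lambda)
  labels are planted with clearly separated FPKM laws around the 5000
  floor; peaks comprise exponential background, promoter-resident decoys,
  and 12 spaced-out super clusters of 3–5 high-RPM peaks.

What the generator does **not** emulate: breakpoint micro-homology
sequence context, GC/replication-timing covariates of CNA noise,
subclonal phylogenies (VAF is drawn per event, not per clone), covariate
correlation structure beyond the planted interactions, and informative
censoring. Passing round-trip tests therefore demonstrates that the
detectors recover what they claim under the stated statistical model —
not that the thresholds themselves are optimal for any particular real
cohort.

## Problem sizes and numerics

Round-trip tests run on cohorts of 60–250 samples; the headline proximity
measurement uses 1000 samples (≈ 230 MYC-type events), chosen so the
binomial 95% CI on the adjacency fraction is a few percentage points wide.
Survival recovery uses 200 replicates at n = 500 with ~30% censoring, and
the permutation calibration 500 cohorts at B = 200 — B scaled down from
the production default of 1000, which only coarsens the p-value grid, not
its calibration. The Newton solver converges to |step| < 1e-12 with an
explicit separation error; binning oracles agree to 1e-12 (exact
floating-point agreement is not asserted because summation orders differ).
All stochastic procedures take explicit seeds and are bit-reproducible.

## Known limitations

* The homology filter is ungapped; a gapped aligner could in principle
  flag diverged repeats the window scan misses.
* `breakpoint_boundary_proximity` treats the end of the last segment as a
  boundary when the final state is non-neutral; with whole-chromosome
  segments this places boundaries at chromosome ends.
* The elbow cutoff (slope-1 tangent) and the chord-distance criterion can
  legitimately disagree on curves without a sharp inflection; agreement is
  guaranteed only in the planted-elbow regime.
* Multivariate Cox fits inherit lifelines' behaviour for near-separated
  covariates; the explicit separation error is only raised by the
  single-covariate permutation engine.
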
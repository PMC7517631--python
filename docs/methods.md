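# Methods

## Data model and normalization

The pipeline consumes transcript-level quantifications in the Salmon
`quant.sf` dialect (Name, Length, EffectiveLength, TPM, NumReads) for a
paired design: each of `P` patients contributes one sample per condition
(pre-ischemia, ischemia, reperfusion). Counts are converted to TPM within
each sample — `rate_t = count_t / efflen_t`, scaled so each column sums to
10⁶ — and log₂-transformed with **no pseudocount**: a zero TPM is treated
as undefined rather than shifted, matching the decision to remove zeros
instead of compressing them into the signal.

Because the per-condition group sizes are small, each transcript is
summarized by the **median** log₂ TPM over that condition's samples
(midpoint convention for even counts). A condition median is computed over
the defined samples only and is undefined only when every sample of that
condition is zero; a transcript is removed when any condition is entirely
undefined (sporadic dropouts are tolerated; the stricter "any zero removes
the transcript" rule is available via configuration). A low-signal filter
then removes transcripts whose **maximum** condition median is below
log₂ 3 ≈ 1.585 — maximum rather than mean, so that transcripts induced in
only one condition survive; mean aggregation is available as an option.

Gene-level aggregation (for the differential-expression branch, when a
transcript-to-gene map is supplied) sums member counts and uses the
count-weighted mean effective length, falling back to the unweighted mean
for all-zero genes. Unmapped transcripts are carried through under their
own identifiers, with a warning, rather than silently dropped.

## Hexagonal batch SOM

The trajectory clustering uses a batch self-organizing map on a 7 × 7
offset-hexagonal lattice (49 modules; interior nodes have six neighbors).
Per epoch, each input row is assigned to its best-matching unit (Euclidean
nearest codebook vector; ties resolve to the lowest module index) and each
codebook vector is replaced by the neighborhood-weighted mean of all rows,
with Gaussian lattice weights exp(−d²/2σ²). The radius σ decays linearly
from 3 to 2 lattice units over 100 ordering epochs and holds at 2 for 50
tuning epochs. With all radii at zero the update degenerates exactly to
Lloyd's algorithm (k-means), which the tests exploit as an oracle: the
per-epoch quantization error (mean distance of rows to their BMU) is then
non-increasing.

Three deliberate choices differ from the most common SOM recipes, each
driven by how the module means are consumed downstream:

* **Input space.** The SOM clusters **per-transcript centered** profiles
  (each 3-vector of condition medians minus its own mean), i.e. trajectory
  *shape*. On raw profiles the between-transcript abundance spread
  (log-normal, sd ≈ 2 log₂ units) dominates the Euclidean metric and the
  49 modules mostly tile the abundance diagonal, mixing trajectory classes
  within modules. Centering removes that axis from the clustering space
  only; the module summaries that the selection rules test are still
  computed from the raw (uncentered) profiles, so the rules keep their
  absolute-TPM meaning. Raw-space clustering remains available
  (`som_input: raw`).
* **Initialization.** The codebook is initialized deterministically on the
  plane of the top two principal components (spread to ±2 sd), the
  classical linear initialization. Random row-sampling initialization is
  available (`init: sample`) but produces occasional badly-ordered maps
  whose boundary modules mix classes.
* **No zero-radius polish by default.** A final σ = 0 (k-means) polish
  spreads codebooks into the tails of each data cluster; modules that
  capture a tail can fall on the wrong side of a ±1 log₂ selection
  threshold even when the class as a whole clears it. Keeping a residual
  neighborhood (σ = 2) holds a cluster's modules near the cluster centre,
  which stabilizes the module means. The polish is available
  (`epochs_polish`) and is used by the k-means-limit tests.

Module ids run row-major from 1 (bottom-left) to 49 (top-right). This is a
labeling convention, not a claim about any particular published map's
numbering. Empty modules are allowed, reported, and select into no
cluster. The U-matrix (distance between lattice-adjacent codebooks, and
per-module mean over neighbors) is written for map diagnostics.

## Module selection rules

Each non-empty module is summarized by its condition means P̄, Ī, R̄ over
member transcripts, by default the **geometric** mean TPM (the arithmetic
mean of the members' median log₂ TPM, exponentiated). The geometric mean
weights every member's fold-change equally; the arithmetic linear-scale
mean (`module_mean_scale: linear`) is dominated by the brightest members
under the heavy-tailed abundance distribution, which makes module ratios
noisy. The four rules in the table in the README are applied at threshold
t = 1 (2-fold). Up- and down-rules for the same effect are mutually
exclusive for any t > 0; an ischemia rule and a reperfusion rule can both
fire for one module, in which case the module is reported in both clusters
together with an overlap table — disjointness is not enforced.

The down-rules mirror the up-rules with a negated threshold (≤ −t). A
literal variant with ≤ +t (`literal_table1: true`) is kept for comparison
with tabulations in which the minus sign was lost typographically; it is
near-vacuous (almost every module satisfies ≤ +1) and not used by default.

Modules with an undefined or non-positive condition mean are excluded from
selection with a warning, since their log ratios are undefined.

## Differential expression

The DE branch is a deliberately simple two-group negative-binomial Wald
test, not a reimplementation of a full DE framework — no fold-change
shrinkage, no outlier or independent filtering. Counts are normalized by
median-of-ratios size factors (median over features with a positive
geometric mean of count/geometric-mean). Per feature, dispersion α in
Var = μ + αμ² is estimated by method of moments from the within-group
pooled variance, floored at 10⁻⁸, and **moderated**: the per-feature
estimate is averaged with the across-feature median with prior weight
df₀ = 20 pseudo-degrees-of-freedom. Without moderation the Wald statistic
at 5 + 5 samples is t-like (≈ 8 df) and the nominal-0.05 type-I error
inflates to ≈ 0.085; with moderation it measures ≈ 0.054–0.073 across
simulation seeds (slightly anti-conservative, from plug-in means in the
standard error). The log₂ fold-change adds a pseudo-mean ε = 0.5 to the
normalized group means inside the logarithm only, so fold-changes stay
finite at zero counts without biasing the test; features all-zero in both
groups are flagged untestable (p = 1, log₂FC = 0).

Significance follows the conventional raw-p rule — |log₂ FC| ≥ 1 and
p < 0.05 — while Benjamini–Hochberg adjusted p-values are reported
alongside. A paired variant (one-sample t-test on within-patient log₂
ratios) matches the paired biopsy design; the default is unpaired.

Note an intrinsic property of median-of-ratios normalization that the
tests make explicit: a fold-change shared by *all* features is absorbed
into the size factors, and a large asymmetric fraction of changed features
biases the factors. Calibration scenarios therefore spike fold-changes
into a minority of features over a null background.

## Gene-set over-representation

For each cluster and gene set, the overlap k is tested against the
hypergeometric null: p = P(X ≥ k), X ~ Hypergeom(N = universe, K = set ∩
universe, n = cluster ∩ universe) — Fisher's exact right tail, computed
via log-gamma arithmetic (stable to N ≈ 10⁶). Only over-representation is
tested. BH adjustment is applied within each cluster's family of sets, and
a set is called enriched at adjusted p < α = 0.05. The default universe is
the set of transcripts retained after filtering ("measured"), the least
anti-conservative choice when the true screening background is unknown; a
collection-derived universe is available.

## Synthetic data generator

The generator emulates the paired study design: per transcript a
log-normal baseline abundance (log₂ mean 8, sd 2 — a realistic bulk
RNA-seq dynamic range around a few hundred TPM for ~4000 transcripts), a
per-class condition multiplier, and a multiplicative log-normal patient
effect (sd 0.2 natural-log units) shared across a patient's three
samples. Within each sample, expected reads are allocated proportionally
to abundance × effective length (lengths uniform on 200–5000 bases, fixed
across samples) and scaled to a library size of 2 × 10⁶; observed counts
are negative binomial via a gamma–Poisson mixture with dispersion 0.1
(Var = μ + αμ²), Poisson in the α → 0 limit. Everything is deterministic
given the seed.

The default class mix is 2000 flat transcripts plus four 500-transcript
classes with symmetric 4-fold multipliers: ischemia-up (1, 4, 4),
ischemia-down (1, ¼, ¼), reperfusion-up (1, 1, 4), reperfusion-down
(1, 1, ¼).

**Compositionality.** TPM is a relative measure, and the planted classes
are not mass-balanced: total expected abundance is ≈ 1.28× baseline in
ischemia and ≈ 1.56× in reperfusion, so every transcript's TPM is deflated
by ≈ 0.36 and ≈ 0.64 log₂ in those conditions — the flat class is
*observed* at ≈ (−0.36, −0.64) in (log₂ I/P, log₂ R/P) space, and the
planted 2.0 log₂ up-ratios are realized at ≈ 1.3–1.6. Rescaling a
condition's multipliers cannot remove this (per-sample normalization
cancels any global factor); it is an intrinsic property of relative
abundance data that real TPM analyses share. The symmetric 4-fold
multipliers were chosen so every class still clears its selection rule
with margin after this deflation.

Gene-set simulation emits one planted set per non-flat class (80% of the
class members plus random fillers up to the class size, by default) and
uniform decoy sets, recording which cluster each planted set should
enrich. `evaluate_recovery` scores per-class recall (planted transcripts
recovered by the matching cluster) and precision (cluster members that
are planted; flat transcripts count as false positives).

## What the synthetic tests do and do not show

Passing the end-to-end recovery test (recall ≥ 0.9, precision ≥ 0.8 per
class at the default seed; the acceptance script reports the same
quantities for any seed) shows that the chain
TPM → medians → filter → SOM → rules → enrichment correctly recovers
planted, well-separated trajectory classes under realistic count noise, a
paired patient effect, and compositional distortion. It does **not** show
that real tissue yields classes this clean: real trajectories form a
continuum, dispersion varies per gene, and library composition shifts are
confounded with biology. Three quantified fragilities at the default study
size (measured over 20 simulation seeds): (1) the compositional drift
places the flat background within ≈ 0.9σ of the down-rules' R̄/P̄
threshold, so small modules capturing the flat class's noise tail can
genuinely pass a down rule; this leaves worst-class precision anywhere
between ≈ 0.76 and 0.99 (≥ 0.8 on 16 of 20 seeds). (2) Map ordering can
occasionally fold so that one class's modules straddle a threshold:
worst-class recall was ≥ 0.96 on 19 of 20 seeds and 0.78 on one. (3) The
NB Wald test runs slightly hot (≈ 0.06 at nominal 0.05) at five samples
per group.

## Pipeline, determinism, and outputs

`run_pipeline` executes normalize → (three DE contrasts: ischemia vs
pre-ischemia, reperfusion vs ischemia, reperfusion vs pre-ischemia) and,
in parallel conceptually, SOM → selection → enrichment. One global seed
fans out to named per-stage seeds via `numpy.random.SeedSequence.spawn`,
and with the default PCA initialization the SOM itself is seed-free, so
identical configurations produce byte-identical TSV outputs. All tables
are single-header TSVs with floats at six significant digits. A failing
stage aborts with the stage name, leaves partial outputs, and writes a
`FAILED` marker; a completed run writes `report.json` with input hashes,
the full configuration, per-stage seeds, row counts at each filter, and
cluster/DEG/enrichment summaries.

Problem sizes used by the test suite and acceptance script — 4000
transcripts × 15 samples for recovery, 2000 features for DE calibration,
universes ≤ 12 for exhaustive Fisher enumeration, 1000 random vectors for
the BH oracle — were chosen so the whole suite completes in seconds while
keeping every estimate's Monte-Carlo error well inside the asserted
bands.
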
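# Methods

This note records the models, algorithmic choices, parameter defaults
and limitations of `nirauth`. It is written for users deciding whether
the pipeline's behaviour on synthetic cohorts transfers to their own
instrument data.

## Problem setting

A two-class authentication task: `n` samples measured by FT-NIR on a
common wavenumber grid (absorbance units), each labelled positive
(protected origin) or negative (any other origin). The pipeline's output
is a binary classifier plus prediction-set sensitivity and specificity.
Class sizes are typically unbalanced (the default study design is
450/120) and a few percent of scans are aberrant — measurement faults or
atypical samples — which must be removed before modelling.

## Stage order

trim → per-class outlier removal (on raw trimmed spectra) → one
pretreatment → per-class Kennard–Stone split (on the pretreated
features) → MCCV latent-variable selection → final PLSDA fit →
prediction-set metrics.

Outliers are diagnosed on raw spectra because pretreatments such as SNV
deliberately compress exactly the gross variation that makes aberrant
scans visible. The split runs on the pretreated features because the
split should span the feature space the model actually sees
(`split_on_preprocessed: false` switches to raw-based splitting, which
makes the split identical across pretreatment arms in a comparison).
Both choices are configuration-visible and echoed in the run report.

## Stahel–Donoho outlyingness

For sample `x_i` and unit direction `a`:

    out(x_i) = max_a |a.x_i − med_j(a.x_j)| / (1.4826 · MAD_j(a.x_j))

The exact supremum over all directions is intractable for p ≈ 2600; the
standard stochastic scheme maximises over 500 random Gaussian unit
vectors plus up to 500 normalised pairwise differences (pair differences
point at outliers, which is what makes the maximisation effective in
high dimension). Directions with scaled MAD below 1e−12 are skipped.
A sample is flagged when its score strictly exceeds the cutoff
(default 3.0 ≈ "beyond 3 robust standard deviations"); a score exactly
at the cutoff is kept. Diagnosis runs within each class: a minority-class
sample must not look aberrant merely because the pooled median sits in
the majority class. The direction seed is mandatory and recorded.

Caveats. With very small classes (≲20 samples) the per-direction MAD is
noisy and clean samples can exceed 3; the cutoff is calibrated for
cohort sizes in the hundreds. On tiny two-dimensional configurations the
true supremum has razor-thin angular spikes that no finite direction
scheme reproduces; the test suite therefore checks oracle agreement on
configurations with a stable projection scale in every direction.

## Pretreatments

* **SNV**: per-spectrum `(x − mean)/sd`, sample sd (ddof = 1). Exactly
  invariant to per-spectrum affine distortion `a·x + b`, `a > 0` — hence
  removes multiplicative scatter and additive offsets. Rows with zero sd
  are an error.
* **D2**: Savitzky–Golay second derivative, default window 11 points,
  polynomial order 3, scaled by 1/Δ² (Δ = grid spacing in cm⁻¹).
  Annihilates any per-spectrum polynomial baseline of degree ≤ 1
  exactly; implemented as SG rather than finite differences because
  finite differences amplify noise unrealistically at ~2 cm⁻¹ spacing.
* **Smoothing**: Savitzky–Golay with derivative order 0, default window
  11, order 2.

Edges are handled by evaluating the boundary-fitted local polynomial, so
the output keeps all p columns. Exactly one pretreatment is applied per
model run — they are compared as alternatives, not chained.

## Kennard–Stone splitting

Deterministic maximin selection under Euclidean distance: start with the
most distant pair, then repeatedly add the candidate maximising the
minimal distance to the selected set. Ties break to the lowest index at
every step so the split is fully reproducible. The selection runs
independently within each class (training fraction default 0.696, or
explicit per-class counts) and the per-class selections merge into one
training and one prediction set.

## PLSDA

Class coding: positive → (+1, −1), negative → (−1, +1); both X and the
coded Y are mean-centred, never autoscaled (spectral channels share
units; autoscaling would inflate noise wavelengths). The PLS fit is
SIMPLS (de Jong 1993); because SIMPLS extracts components from the
cross-product matrix without deflating X, a model fitted with A
components yields the fit for every a ≤ A by truncation, which the MCCV
loop exploits (one fit per split instead of one per candidate count).
For the rank-one coded Y used here SIMPLS coincides with NIPALS PLS2;
the test suite verifies coefficient agreement with an independent NIPALS
implementation to 1e−6 and equality with ordinary least squares at full
rank to 1e−8.

Classification: positive iff the first predicted response strictly
exceeds 0 (a response of exactly 0 is assigned negative). The second
response column is the negation of the first and is kept for
diagnostics only.

**Latent-variable selection.** T = 20 Monte-Carlo repetitions; each
draws a stratified 50/50 split of the training set (stratification
prevents degenerate single-class secondary sets under class imbalance;
one global permutation is drawn per repetition and partitioned within
class, which makes the rate exactly invariant under renaming the
classes). The misclassification rate per candidate count a is the
average percent rate over repetitions,
`MR(a) = (1/T) Σᵢ Mᵢ/Pᵢ × 100%` — the average, not the bare sum of
per-split rates, so the number reads as a percentage; the argmin over a
is unaffected. The smallest count attaining the minimum wins.
`max_lv` defaults to 20; if the data's numerical rank is exhausted
earlier (common for synthetic cohorts whose clean variation is low-rank
by construction), the candidate grid is truncated to the extractable
count rather than failing.

**Metrics.** Sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`,
positive class = protected origin; reported to 3 decimals in pipeline
output, unrounded internally. Runs with no positive (or no negative)
evaluation objects are an error rather than a silent NaN.

## Synthetic cohort generator

Each clean spectrum is a sum of 8 Gaussian absorption bands between
4300 and 8400 cm⁻¹ on the instrument grid (4000–12000 cm⁻¹, step
1.928 cm⁻¹, ≈4150 points), with two bands in the 4000–5000 cm⁻¹
combination region shifted −0.06/−0.05 AU for the negative class
(scaled by `effect_size`) — emulating the lower absorbance of
non-protected samples there. Nuisance variation per sample:

* multiplicative scatter on the systematic spectrum (sd 0.06),
* additive linear baseline (intercept and slope, sd 0.008 AU),
* correlated band-amplitude jitter via two compositional factors
  (sd 0.005 relative),
* i.i.d. Gaussian detector noise (sd 1e−5 AU, the floor of a 64-scan
  averaged FT-NIR measurement).

The scatter, baseline and jitter draws all derive from a single
per-sample latent point distributed uniformly on a disc, so clean
within-class variation is bounded and exactly rank-2. This mirrors two
properties of real replicate scans — nuisances are physically coupled
(particle size and packing drive scatter and baseline tilt together)
and bounded — and it is what makes the outlyingness cutoff of 3 a
clean separator on generated data: along every projection direction a
clean cohort stays within ≈2.3 robust standard deviations, so any flag
on generated data is attributable to an injected aberration.
Independent, unbounded per-nuisance draws would instead let a
450-sample cohort's extremes reach 3–4 robust sds and blur the
clean/aberrant distinction the generator exists to provide.

Aberrations: a seeded fraction of samples (default 4%) receives one of
three faults — a giant Gaussian spike (height 1–2 AU) at a random
wavenumber, a baseline step jump (±0.3–0.6 AU) at a random position, or
a ×5 scatter blow-up — and is recorded in a ground-truth mask. Spike and
step positions are drawn over the full instrument range, so a fault can
land entirely inside the discarded 9000–12000 cm⁻¹ region; such a scan
is clean after trimming, which is why recovery statistics are computed
on full-range data while the pipeline itself trims first.

What the generator does *not* emulate: physically assigned overtone/
combination band positions, instrument line-shape effects, wavelength
drift, temperature/moisture dependence, and heavy-tailed or
high-dimensional within-class composition variation. Consequences for
interpreting the tests: the pipeline's perfect synthetic sensitivity/
specificity shows correctness of the machinery, not expected field
performance; on real cohorts (higher-rank, heavier-tailed variation)
the outlier diagnosis will flag a few genuine-but-extreme samples, more
latent variables will be needed, and metrics below 1 are normal.

## Null calibration

With `effect_size = 0` (or permuted labels) the minimal MCCV rate sits
at chance. Chance is 50% only for balanced classes: under the 300/80
production imbalance a no-signal PLSDA predicts the majority class and
the rate floor is ≈21% by arithmetic. Null checks therefore use
balanced cohorts (120/120), where the observed minimal rates are
45–53%.

## Numerical choices

* SNV degenerate rows, all-degenerate SDE projections, empty trim
  intervals, classes shrinking below 3 samples, and undefined
  sensitivity/specificity all raise errors naming the offending sample
  or stage; the pipeline aborts without partial outputs.
* SIMPLS declares rank exhaustion when the deflated cross-product's
  singular value drops below 1e−12 of its initial value.
* Kennard–Stone ties and MCCV argmin ties resolve to the lowest
  index/count.
* Reports contain no timestamps; identical configurations produce
  byte-identical reports, and all randomness flows from named seeds.

## Problem sizes used in the test suite

Unit and property tests run on toy matrices (n ≤ 60) and desk-scale
cohorts (90–150 samples); the end-to-end recovery and null checks run
the full 450/120 default cohort on the ≈4150-point grid. The complete
suite finishes in well under a minute on one CPU.
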
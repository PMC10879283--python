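# Methods

`ftdx` implements a differential-diagnosis pipeline for the three core
frontotemporal-dementia syndromes — behavioral-variant FTD (bvFTD) and
the semantic (svPPA) and nonfluent (nfvPPA) variants of primary
progressive aphasia — from parcellated structural-MRI morphometry. The
pipeline consumes a subject × 735 feature table (360 cortical-patch
mean thicknesses, 360 cortical-patch volumes, 15 subcortical volumes)
plus per-subject metadata, and runs four stages: w-score harmonization,
a parallel multi-type feature-embedding neural classifier under nested
cross-validation with inner-fold ensembling, Integrated-Gradient
feature attribution, and patch-wise statistical mapping. Because the
clinical cohorts this design targets are access-restricted, the package
ships a synthetic-cohort simulator with known ground truth; all
quantitative validation runs against planted truth.

## Feature schema

The atlas registry fixes the column order: left-hemisphere cortical
patches, right-hemisphere patches (180 each), then 15 subcortical
structures (7 bilateral pairs — thalamus, caudate, putamen, pallidum,
hippocampus, amygdala, accumbens — plus brainstem). Real HCP-MMP1 label
strings may be supplied; the default uses systematic placeholders
(`L_ROI_001` …) so the pipeline runs without surface geometry. Feature
columns carry type prefixes (`thk_`, `cvol_`, `svol_`); tables are
CSV, joined to metadata on `subject_id`. Missing values are rejected,
never imputed.

## W-score harmonization

Each feature `x_f` is regressed by OLS on covariates using only the
reference diagnostic group (bvFTD, the largest class — no healthy
controls are assumed available), and every subject is re-expressed as

    w_if = (x_if − design_i · β_f) / σ_f,

with `σ_f` the reference residual SD using an `n_ref − p` denominator.
Default covariates: age, sex, TIV and a combined cohort × scanner
factor (scanner nested within cohort), all dummy-coded against the
lexicographically smallest training level. TIV is regressed from all
feature types uniformly; the generator gives thickness no TIV
dependence, so its fitted TIV slope is simply ≈ 0 there. Assumptions:
linear covariate effects, additive site offsets, homoscedastic Gaussian
residuals within the reference group.

Properties used by the tests: on the reference training rows the
w-scores have exactly zero mean and sample SD `sqrt((n_ref−p)/(n_ref−1))`
per feature, and they are exactly orthogonal to every design column —
in particular the cohort indicator — by OLS geometry. On held-out rows
the expected cohort effect is zero, but its *estimate* carries sampling
noise of order `σ·sqrt(1/n_a + 1/n_b)` from the finite reference fit,
about 0.07 in w-units at n = 500; batch-removal checks on held-out rows
therefore compare against the raw-data effect size (a > 10× shrink)
rather than an absolute near-zero threshold. Unseen categorical levels
at transform time map to the reference level with a logged warning.
Degenerate inputs: rank-deficient designs and zero-variance features
raise named errors rather than propagating NaNs.

## Classifier

A two-level multilayer perceptron with parallel type-specific arms:
thickness 360→128→32 and volume (cortical + subcortical) 375→128→32,
embeddings concatenated (64) and fused through 32 hidden units to 3
logits. ReLU activations, dropout 0.2 after every hidden layer, He
initialization from an explicit seed. The exact published layer widths
are not machine-readable from the source figure; these defaults form a
gentle funnel sized for n ≈ 277 and are fully configurable. The
ablation baselines are: naive concatenation (one stack
735→256→64→32→3, i.e. the same number of levels), thickness-only
(360→128→32→32→3) and volume-only (375→128→32→32→3).

Training: plain SGD, learning rate 1e−3, L2 weight decay 1e−5,
minibatch 32 (8 in reduced-size test fixtures so the SGD step count
remains adequate), weighted cross entropy with inverse-frequency class
weights rescaled to mean 1 (weighted-mean reduction, so a singleton
batch's weight cancels). Up to 300 epochs; when a validation split is
supplied, the checkpoint with the best validation overall balanced
accuracy is kept, with early-stopping patience 30. All stochasticity
(init, shuffling, dropout) flows from one seeded generator, so fits are
bit-reproducible. The network and its backpropagation are written
directly on numpy: the model is a handful of small dense layers, and an
explicit implementation keeps the package light, deterministic, and
provides input gradients for attribution; gradients are verified
against finite differences in the tests.

## Nested cross-validation and ensembling

Stratified 10-fold outer split (per-fold class counts deviate from
perfect stratification by ≤ 1). Within each outer fold the non-test 90%
is partitioned by a stratified 9-fold split whose nine rotations give
nine (≈80% train / ≈10% validation) inner splits — matching the
80/10/10 description and producing exactly nine models, whose mean
softmax is the outer-fold prediction (argmax ties break to the lowest
class index). The harmonizer is fit once per outer fold on the non-test
90% and applied with frozen coefficients to all rows; fitting it once
per fold (rather than per inner split) keeps the nine members
comparable, and fitting on the 90% is the only row set consistent with
"once per fold" given that the inner 80% train portions rotate. A
leakage audit re-runs a fold with test-row features perturbed and
requires bit-identical harmonization coefficients and network
parameters; a deliberate all-rows harmonization fit is the audit's
negative control.

Balanced accuracy is per-class one-vs-rest (sensitivity+specificity)/2
from the confusion matrix pooled over the ten outer test sets (per-fold
values are also reported for dispersion); overall balanced accuracy is
the mean over the three classes. Note this is *not* macro-recall.

## Integrated Gradients

Midpoint-rule Riemann approximation of the path integral of the target
logit's input gradient, multiplied by (x − baseline); 128 steps by
default (completeness residual < 1% of the logit gap at 256 steps on
trained networks; exact for linear models at any step count). The
attribution target is the subject's true class, pre-softmax.
Population maps average over all subjects of a subtype and the nine
ensemble members.

Baseline choice: population maps default to the grand-mean w-score
vector of the analyzed table (an "average patient"). The superficially
natural all-zero w-score vector is *not* neutral here: since bvFTD is
the harmonization reference, zero-w is precisely the bvFTD prototype,
and an IG baseline equal to a class prototype suppresses attributions
toward that class (for bvFTD subjects every informative feature sits at
the baseline, so x − x' ≈ 0; in the recovery experiment the bvFTD map's
overlap with planted truth was at chance with the zero baseline and
recovers with the grand-mean baseline). The zero baseline remains
available through the `baseline` argument.

## Statistical mapping

Per feature, OLS of the (harmonized, by default) feature on an
indicator of one diagnosis vs the pooled others plus age, sex and
education, with a two-sided t test on the indicator. The 735 fits are
vectorized through one least-squares solve; one feature is
cross-checked against statsmodels in the tests. Benjamini–Hochberg
control at FDR 0.05 runs per feature-type family: thickness (360
tests) and volume (360 cortical + 15 subcortical = 375 tests), the
subcortical tests sharing the volume family. Recovery scoring counts
sensitivity over *detectable* planted patches: a patch planted with the
same effect in all three subtypes has an exactly zero one-vs-rest
contrast and is unrecoverable in principle (the default topography
contains two such patches); false discoveries are detections outside
the set of features with truly nonzero contrast.

## Synthetic cohorts

The generator emulates a pooled two-consortium clinical sample:

- class sizes 173 bvFTD / 63 nfvPPA / 41 svPPA (the published cohort
  composition, 62.5/22.7/14.8% of 277);
- age ~ N(63.7, 7.7²) truncated to [40, 90]; 54.5% male; education
  ~ N(16, 3²) truncated at ≥ 8 (no published distribution; a plausible
  clinical-cohort default); TIV ~ N(1.45·10⁶, 1.3·10⁵ ²) mm³;
- two cohorts assigned 47.3/52.7%, three scanners per cohort;
- per-feature baselines (thickness ≈ 2.5 mm, cortical patch volume
  ≈ 3000 mm³, subcortical ≈ 4000 mm³), linear age slopes, a male
  offset, and a TIV slope on volume features only;
- additive per-feature cohort and scanner offsets drawn once per
  simulation; relative to measurement noise the volume-type offset
  (1.0× noise SD) is 3× the thickness-type offset (0.33×), reproducing
  the volume-dominant site bias seen in multi-site morphometry;
  scanner offsets at half the cohort scale (free parameters — no
  published scanner-level magnitudes exist);
- subtype atrophy as a negative shift of d × noise-SD (default d = 2)
  on a fixed patch topography: bvFTD bilateral frontal/insular, nfvPPA
  strongly left-lateralized inferior-frontal, svPPA left-dominant
  anterior-temporal plus left hippocampus/amygdala, with partial
  overlap between subtypes; atrophy hits both the thickness and the
  volume feature of a planted patch;
- i.i.d. Gaussian noise per feature type (0.15 mm / 300 mm³ / 200 mm³).

Not emulated: spatial correlation between neighboring patches,
subject-level atrophy-severity heterogeneity, scanner drift,
non-Gaussian measurement error, missing data. Passing recovery tests
therefore show the pipeline's statistical machinery is correct under
its own assumptions, not that the published accuracies transfer to any
real cohort.

## Validation experiments and problem sizes

`ftdx.experiments` fixes the conditions shared by the test suite and
`scripts/acceptance.py`:

- harmonization check: n = 500 (published class proportions);
- leakage audit: n = 72 reduced cohort, 4 outer folds;
- classification recovery: the full 277-subject conditions at d = 2,
  10-fold nested CV (max 200 epochs), plus a label-permuted control
  (100 epochs) that must stay at chance;
- architecture comparison: complementary-signal topography (bvFTD
  separable only through thickness, nfvPPA only through volume, svPPA
  through half of each) at the study's cohort composition and
  optimizer regime, paired runs of the parallel-fusion and
  naive-concatenation models on shared splits and equal budgets across
  seeds;
- attribution recovery: 150 subjects/class, one outer fold's ensemble
  (max 150 epochs), IG at 64 steps, top-20 thickness patches scored
  against planted truth over 5 seeds;
- statistical-mapping recovery: 20 simulations at 150 subjects/class.

These sizes are the package's own reproduction scale, chosen so the
whole suite runs on one CPU core in minutes; they are smaller than the
sizes a full study would use, and the tolerance bands in the tests
account for that.

A negative result worth stating plainly: on these synthetic cohorts
the naive-concatenation baseline consistently matches or slightly
exceeds the parallel-fusion model (typical margin 0.02–0.08 overall
balanced accuracy across scales, effect sizes and training budgets).
With conditionally independent features, a single concatenated MLP can
exploit the same sparse signal as the type-separated arms while having
roughly twice the first-layer capacity, so the structural prior of
parallel embedding buys nothing here. The advantage that parallel
fusion shows on real clinical data plausibly rests on properties this
simulator deliberately omits — spatial correlation among neighboring
patches and redundancy between the thickness and volume measurements of
the same region. The corresponding comparison test encodes the
expected real-data ordering and currently fails on synthetic data; it
is kept as an honest marker of this gap rather than weakened.

## Known limitations

- The published per-class accuracies (0.797/0.819/0.892) are properties
  of access-restricted clinical data; this package verifies arithmetic
  identities on those printed values and full behavioral recovery on
  synthetic data only.
- The harmonization assumes additive site effects; multiplicative
  (scale) site differences would require a variance-harmonizing
  extension, deliberately out of scope.
- Population-mean signed IG maps for the harmonization reference class
  are intrinsically attenuated (see baseline discussion); magnitude
  maps or a healthy-control reference would sharpen them.
- No spatial model: patch-wise tests and attributions treat patches as
  exchangeable; no cluster-level correction or surface smoothing.
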
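# Methods notes

This note records the modelling choices behind `vbmsvm`: what each stage
assumes, which defaults matter and why, what the synthetic cohorts do and
do not emulate, and the numerical conventions a careful reader would want
pinned down.

## The classifier

The core model is a linear hard-margin SVM on masked, smoothed gray-matter
voxel values.  "Hard margin" is realised as a soft margin with a very
large finite box constraint (C = 10⁸ by default) plus an explicit
post-fit check: if any dual coefficient saturates the box while its margin
is violated beyond `kkt_tol` (10⁻⁴), the fit raises a "not separable"
error naming the offending subjects rather than silently returning a
slack solution.  With p ≫ n smoothed features the data are separable in
practice, so the bound is never active on image features.

The dual is solved on the n×n Gram matrix, never in voxel space.  Two
solver paths share one contract (the KKT conditions, which the test suite
verifies against a generic QP oracle):

* an **active-set method** for the hard-margin regime (C ≥ 10⁶): start
  with every point constrained to the margin, solve the equality KKT
  system, prune points whose dual coefficient goes negative and re-add
  points whose margin falls below 1, until the full KKT conditions hold.
  A tiny ridge (10⁻¹² of the mean Gram diagonal) keeps the linear systems
  nonsingular under duplicated subjects; its perturbation is far below all
  stated tolerances.  Chunked moves converge in a handful of cycles; after
  40 cycles moves drop to one element at a time to break potential cycling,
  and a cycling cap falls back to
* an **SMO solver** (maximal-violating-pair working-set selection), which
  also handles moderate C (the soft-margin TIV-only mode).

Both are numba-compiled; the first call in a session pays the JIT cost.
Solutions are deterministic given the input order.  Ties at f(x) = 0
predict −1 (control) — an arbitrary, documented convention.  No feature
centering or scaling is applied to image features; covariate
residualisation is the only transformation, and only when requested.

Leave-one-out CV uses the support-vector shortcut: a left-out subject with
α = 0 and margin strictly above 1 + `kkt_tol` cannot change the
maximum-margin solution, so the full model's score is reused; all other
folds are retrained (warm-started from the full model's support set).  The
shortcut is score-identical to the naive loop within 10⁻⁶ (tested).

## Covariate removal

Covariates (age, sex indicator, TIV; intercept always included) are
removed by the residual-forming projection R = I − X(XᵀX)⁻Xᵀ, applied to
the features.  Two modes exist because published analyses rarely state
which they used:

* `foldwise` (default): the projection's coefficients are estimated on the
  training rows of each CV fold only and applied to all rows — no
  information from the held-out subject enters the projection;
* `pooled`: one projection fitted on all subjects before CV.

Both are reported in the output.  Rank-deficient designs fall back to the
pseudo-inverse with a logged warning.  Under label permutation, covariates
travel with their subjects (they are not permuted): the exchangeability
question is whether the group assignment is informative given the images.

## Inference conventions

Permutation p-values use the add-one convention p = (1 + #{null ≥
observed}) / (1 + N), which is valid (never zero) and reproduces
bound-style reporting — with N = 50,000 the smallest reportable p is
1/50,001 < 2×10⁻⁵.  The voxelwise map tests |w_v| two-sidedly, since
weight maps carry meaningful signal of both signs; it is uncorrected, as
such maps are conventionally displayed (max-statistic familywise
correction would be a natural extension).  Default permutation counts are
desk-scale (999 global, 199 voxelwise); the historical 50,000 / 2,000 are
one flag away and scale linearly in time.

AUC uses midrank tie handling and is computed as the Mann–Whitney
statistic; the ROC threshold sweep collapses tied scores onto single
thresholds so its trapezoidal area equals the Mann–Whitney value exactly.
The DeLong test estimates the covariance of two correlated AUCs from
per-case and per-control structural components; the p-value is two-sided
normal, and per-AUC confidence intervals are Wald on the AUC scale,
truncated to [0, 1].  Identical score vectors give a degenerate
zero-variance difference, which is flagged and reported as p = 1 rather
than divided by.

## The synthetic cohorts

The generator produces the *statistical* structure of a preterm-birth VBM
cohort, not anatomy.  Default design (all overridable):

* 74 cases / 69 controls on a 16³ grid at 1.5 mm isotropic voxels, with an
  ellipsoidal "brain" template (~1,900 masked voxels), preserving the
  p ≫ n geometry while keeping the full pipeline fast enough for
  simulation studies;
* a latent severity s ~ Beta(2, 1.3) per case (controls: 0) that drives
  everything clinical: GA = 36 − 12·s weeks (so GA spans 24–36 and the WHO
  bands map monotonically onto severity), birth weight via a GA trend plus
  a direct severity term, IQ = 102 − 30·s plus noise (~15% of IQ rows
  missing at random, as in real follow-ups); control GA ~ U[37, 42];
* a signed regional effect: two positive and two negative spheres (radii
  2.6–3.2 voxels) added to the template in proportion to severity.  The
  default amplitude (`effect_scale` = 0.054) is calibrated so that an
  oracle knowing the true effect map classifies ≈ 95% of subjects
  correctly — i.e. cohorts are realistically hard, not trivially
  separable;
* a global scale factor per subject (σ = 5%) multiplying the whole map,
  with cases running a 5% mean deficit.  This factor both drives TIV
  (r(TIV, scale) ≈ 0.97 at the default noise) and emulates Jacobian
  modulation; with voxel noise attenuating the raw gap it puts the
  TIV-only classifier in the ~0.7-AUC regime such studies report;
* white Gaussian voxel noise (sd 0.2 in template units before smoothing)
  smoothed with the same 6 mm FWHM kernel as the analysis uses, giving the
  spatial noise correlation of real smoothed GM maps; volumes are clipped
  at 0.  The noise level was chosen jointly with the effect amplitude so
  that the oracle difficulty and the TIV properties above hold together;
* an SGA flag on ~22% of cases, assigned by drawing the birth-weight
  residual (given GA) from the lowest decile, with severity sampled
  independently so SGA subjects span the severity range.

GA is stored as a continuous value (clinical tables would floor it to
completed weeks; WHO stratification here uses the continuous value, and
integer inputs are accepted as exact).

What the generator does **not** emulate: real neuroanatomy, tissue
segmentation, nonlinear registration, scanner artifacts, site effects, or
any spatial autocorrelation structure beyond Gaussian smoothing.  Passing
tests therefore demonstrate that the *pipeline* recovers the structure it
assumes — not that any particular real cohort would behave this way.
TIV in the synthetic world is the gray-matter-map total (no other tissue
segments exist), a documented divergence from real data where TIV sums all
tissue classes.

## The TIV-only classifier and the anti-learning caveat

The single-feature TIV classifier uses the identical trainer for
comparability.  One overlapping feature is essentially never hard-margin
separable, so the operation falls back to a flagged, margin-tolerant mode:
TIV is standardised (an affine transform; decision scores are affine in
TIV either way) and fitted at C = 1.  One behaviour deserves a warning:
when the feature carries *no* signal, leave-one-out accuracy of any
near-chance classifier is biased **below** 0.5 — leaving a subject out
shifts the boundary away from its class (the "anti-learning" artifact).
The test suite asserts chance-or-below under a group-independent TIV
rather than pretending the null sits at exactly 0.5.

## Problem sizes used in the checks

The packaged checks run at sizes chosen for quick desk iteration: solver
oracle comparisons at n ≤ 40, p ≤ 200; permutation calibration with 99
permutations over 200 null cohorts of 40 subjects; DeLong size checks with
2,000 correlated-null replicates at 100 per class; and the
structure-recovery battery over 20 seeds of the default 74/69 design.
All scale knobs (cohort size, grid, permutation counts) are plain
configuration.

## Known limitations

* The hard-margin construction requires separable inputs; heavily
  overlapping feature sets must use a finite C explicitly.
* The voxel p-map is uncorrected for multiple comparisons.
* Split-half validation uses simple per-group random subsampling; no
  stratification beyond group is attempted.
* The DeLong confidence intervals are Wald-type; a logit-scale variant is
  provided but not default.
* Foldwise residualisation inside the permutation loop is supported but
  slow (it cannot reuse the label-free Gram trick across permutations).
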
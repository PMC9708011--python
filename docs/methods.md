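# Methods

`cinempca` implements a prognostic imaging pipeline for 2D+time cardiac cine
MRI: multilinear principal component analysis (MPCA) features from
registered image stacks, Fisher-ranked stepwise feature selection, linear
SVM mortality classifiers per view with dual-view fusion, survival
evaluation against clinical covariates, and reconstruction-based saliency
maps. This note records the model, the parameters that matter, the design
choices made where the design was genuinely open, and what the bundled
synthetic generator does and does not emulate.

## Synthetic cohort model

Each subject carries a latent risk `r ~ N(0, 1)` that drives everything
observable:

- **Images.** Two views (short-axis `SA`, four-chamber `4Ch`), each an
  `S x S x T` stack (defaults 64 x 64 x 20). The background is a crude
  two-ellipse heart template — a left-ventricular disc and an oblique
  right-ventricular ellipse whose cavities contract to a minimum ~40%
  through the cycle (the recorded end-systolic frame) — plus a smooth
  Gaussian-filtered noise field (unit SD). A septal patch between the two
  ventricles, spanning end-systole ± 2 frames, receives an additive
  intensity shift of `effect_size * noise_sd * r` (default effect size 2).
  The whole stack is then moved through a random subject pose (rotation SD
  5°, translation SD 2 px) and the view's three landmarks are mapped through
  the same pose with Gaussian jitter (SD 1 px).
- **Survival.** Event times are exponential with hazard
  `h0 * exp(beta * r)`, administratively censored at 5 years (random
  censoring available behind a flag but off by default, matching a registry
  with complete follow-up). `beta` defaults to 2.0 and `h0` is solved by
  Gauss–Hermite quadrature so the marginal 1-year event probability equals
  the configured prevalence (default 10%). Under these defaults the c-index
  ceiling of the true risk is ~0.87 and the 1-year-label AUC ceiling ~0.90,
  which leaves the end-to-end classifier realistic headroom; the overall
  event rate over the 5-year horizon comes out near 26%.
- **Clinical covariate.** `0.6 * r + 0.8 * N(0,1)`, a stand-in for a
  composite clinical risk score. Its univariable Cox c-index measures 0.71
  at large n — deliberately the strength of a good clinical score, so the
  "does imaging add value on top?" comparison is neither trivial nor
  hopeless.

What the generator does **not** emulate: myocardial motion beyond isotropic
cavity scaling, MRI acquisition physics and scanner-specific intensity
statistics, multi-slice geometry, and non-rigid anatomical variation.
Passing tests therefore demonstrate correctness of the pipeline's
statistics and its ability to recover localized planted signal — not
performance on clinical data.

## Preprocessing

Fixed order: per-subject z-scoring of the full `H x W x T` array (before
masking, so the statistics are not conditioned on the mask), rigid
landmark registration, elliptical masking, local-mean downsampling to one
of {32, 64, 128, 256}.

- The reference pose per view is the generalized-Procrustes mean of the
  development cohort's 3-point landmark sets (iterated align/re-average to
  1e-8), orientation anchored to the first subject. Validation subjects are
  registered to the frozen development reference.
- Registration is least-squares rigid (Kabsch); an isotropic-scale variant
  sits behind `allow_scale` for cohorts with large heart-size variation.
  Bilinear interpolation, zero fill, 0-based (row, col) pixel-centre
  coordinates throughout.
- The heart mask is an in-plane ellipse centred on the reference-landmark
  centroid with semi-axes 2.5x the per-axis landmark spread, replicated
  over frames.

## MPCA

Fitting centres the sample and, per mode, eigendecomposes the mode-n total
scatter of the partially projected unfoldings, retaining the smallest
leading set of eigenvectors whose cumulative eigenvalue fraction reaches
`variance_kept` (default 0.97). One alternating sweep (mode 1, then 2, then
3) is the default; more sweeps are available. Determinism: eigenvalues are
sorted stably, ties keep original index order, and each basis vector's
largest-magnitude component is made positive, so refits are reproducible
across platforms and training-set orderings. Features are core entries
ordered by descending training variance. With singleton trailing modes the
procedure reduces exactly to classical PCA (verified against a covariance
eigendecomposition oracle).

## Selection, classification, cross-validation

Features are ranked by Fisher's discriminant ratio
`(mu1 - mu0)^2 / (s1^2 + s0^2 + 1e-12)` (population variances). Stepwise
inclusion holds out a random stratified tuning set (~50 cases), trains a
linear SVM (C = 1) on the remainder for each k = 1..30, and keeps the k
with the best tuning AUC (ties to the smaller model). Development runs
under repeated stratified cross-validation (defaults 10 rounds x 10 folds)
with MPCA refit, ranking and selection inside each fold's training portion
only. The feature set from the best single fold — carried between folds as
(row, col, frame) triples of the retained core, since fold bases differ —
is refit on the full development set; a flag selects best round-average
instead. Probabilities come from a Platt-style logistic fit on
cross-validated decision values; if the cross-validated slope is negative
(possible on null data), the fit falls back to in-sample margins so the
probability map stays monotone in the decision value. The dual-scan model
concatenates the two views' selected feature blocks and trains one further
SVM. AUC is the tuning and fold metric because it is threshold-free.

## Survival evaluation

Cox proportional hazards via the partial likelihood with Efron tie
handling; Wald CIs. Harrell's c-index is computed by direct pairwise
enumeration semantics (earlier event vs strictly later time; risk ties
count 1/2) and is tested against a brute-force oracle and lifelines.
AIC = 2k − 2·logPL exactly. Nested models are compared by likelihood-ratio
chi-squared. Kaplan–Meier groups split at the median of the *training*
probabilities (frozen for validation; a flag uses the evaluation median).
The 1-year label is death within 1 year; event-free follow-up shorter than
1 year is excluded from ROC computation. Proportional hazards are checked
by correlating scaled Schoenfeld residuals with event-time rank. The
c-index CI in comparison tables is a seeded 1000-resample bootstrap
percentile interval.

## Saliency

A linear classifier's evidence is mapped to voxel space by embedding
weights into a zero core at the selected feature positions and
back-projecting through the mode bases without adding the mean. Two
weightings exist:

- `svm`: the raw hyperplane normal. Correct as algebra, but the normal is
  the class contrast *whitened by the background covariance*, so its
  back-projection need not look like the discriminative anatomy; on the
  synthetic cohorts it provably fails to localize the planted patch even
  with oracle feature selection.
- `contrast` (pipeline default for localization): each feature weighted by
  its signed training class-mean difference. Back-projecting the contrast
  of the top-30 Fisher-ranked features renders the population-level class
  difference the model exploits; using the full ranked set lets the
  separable basis terms cancel away from the true focus.

Thresholding is per sign. The default cutoff is the 95th percentile of each
sign's values; the pipeline's localization stage instead uses half the
per-sign maximum (the full-width-at-half-maximum criterion), because a
fixed top-5% of all positive voxels retains several times more voxel-frames
than a focal region contains, inflating cluster size and bounding Dice
overlap regardless of how well the peak is placed. Binarized maps are
closed with a discrete radius-2 sphere (33 lattice points) over the
(x, y, t) lattice — a per-frame 2D variant sits behind a flag — then
labeled with 26-connectivity; components under `min_size` (default 20
voxel-frames) are dropped. Regional summaries average the signed map over
user-supplied RV/LV/septum masks per frame.

## Pipeline and provenance

The cohort splits 70:30 into development and validation, stratified by
1-year event status. One master seed derives per-stage seeds through a
documented counter scheme. Every fitting call logs the subject ids it
consumed; the audit asserts the validation set never appears before the
final evaluation stage. Rerunning with the same configuration reproduces
all metrics exactly.

## Problem sizes used in tests and the acceptance script

Simulation sizes are chosen to make the checks informative at desk scale:
the planted-signal study runs at n = 500 subjects, 64 x 64 x 20 voxels,
with a single 5-fold development round; null-calibration runs use
n = 400–600 at 32 x 32 x 20; Cox parameter recovery uses n = 2000
two-group exponential draws; oracle comparisons use 100 random instances
of n ≤ 50. Structural checks (10 x 10 fold bookkeeping) run on small
random tensors where the arithmetic, not the signal, is under test.

## Known limitations

- The saliency map is population-level; per-patient attribution is limited
  to overlaying that map on individual anatomy.
- Best-single-fold feature selection is an extreme-value choice and can be
  unstable at small n; the round-mean alternative is gentler but departs
  from the literal development recipe.
- The generator's pose model is rigid; registration quality on deformable
  real anatomy is untested here.
- Cox fits flag, rather than resolve, monotone-likelihood separation.
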
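# Methods

This note documents the statistical procedures `facejudge` implements,
the defaults it ships, and the design decisions taken where the problem
left genuine latitude. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The modelling problem

The target of modelling is the consensus social judgment: for each face
and each named attribute (trustworthy, dominant, ...), the mean of many
raters' 1–7 Likert responses. Only per-face means are modelled; rater-level
variation enters exclusively through the standard error of the mean. The
predictors are "feature spaces": numeric per-face representations such as
a 128-d face-identity embedding, PCA scores of convolutional activations,
or 30 landmark-derived geometric measures. One linear model is fit per
attribute per space.

Two empirical facts shape every analysis choice. First, social judgments
are strongly inter-correlated: a small number of latent dimensions
(typically two to four) accounts for most rating variance across a dozen
or more named attributes. Second, test sets differ from training sets in
faces, raters, and often rating scale — so accuracy must be rank-based
and inference must be resampling-based.

## Model fitting

For ridge and LASSO, λ is chosen by repeated random splits of the
training faces: at each of `n_cv_iterations` iterations a fresh 80/20
train/validation split is drawn (splits are sampled independently per
iteration, not k-fold), each of the 30 grid values is fit on the 80% and
scored on the 20%, and per-λ errors are averaged over iterations. The λ
minimizing mean validation MSE is refit on all training faces. R² and
RMSE are available as alternative selection metrics (RMSE shares MSE's
argmin and is accepted for interface completeness). Grids are log₁₀-
uniform with inclusive endpoints: ridge [1, 10⁵], LASSO [0.01, 100], 30
values each. Ties in selection go to the smallest λ.

Numerical route: the ridge path is computed in closed form from one SVD
per fold (solutions for all 30 λ from a single decomposition), with all
attributes solved simultaneously against a shared split sequence — this
makes selected λs comparable across attributes and keeps 2,000 iterations
cheap. LASSO uses coordinate descent (scikit-learn), warm-started down
the grid. OLS skips selection.

Standardization: features are z-scored with training-fold means and SDs
inside every fold (never with validation or test statistics), and ratings
are centered through an unpenalized intercept. Whether to standardize at
all is switchable (`FitConfig.standardize`); the default is on, which is
what makes a single λ grid meaningful across spaces with different units.
Fold-constant feature columns get unit SD (they carry no signal in that
fold); globally constant columns are rejected.

Defaults: `n_cv_iterations = 2000`, `validation_fraction = 0.20`,
`selection_metric = "mse"`. Tests and the demo pipeline use smaller
iteration counts (20–200) — λ selection on the synthetic worlds is stable
far below the full count, and the full protocol remains one flag away
(`--full-scale`).

## Evaluation

Accuracy is Spearman's ρ (Pearson correlation of average ranks, ties
averaged). Uncertainty: test faces are resampled with replacement
(default 10,000 draws; demo 1,000) and ρ recomputed per draw; reported as
mean ± SD across draws. For multi-image identity sets, each draw first
samples one image per identity uniformly, then resamples identities with
replacement, so no person dominates. Degenerate (constant) resamples are
skipped and counted, not scored as zero.

Chance level: ratings are shuffled across faces (default 10,000 times)
and ρ recomputed; the 95th percentile of this null is the chance
threshold, and the p-value is the plain proportion of null draws ≥ the
observed ρ (a +1/(n+1) smoothed variant is available behind a flag,
default off). An exhaustive-enumeration mode exists for n ≤ 8, used by
the oracle tests. p-values are BH-FDR-corrected across the evaluated
family; the family is per-dataset for attribute evaluations and
all-cells-jointly for cross-prediction matrices (both configurable).
α defaults to 0.05.

All cells of a matrix (and all pairs in an evaluation) share one seeded
resampling stream: the identical sequence of bootstrap index draws and
permutation shuffles is applied to every cell. This makes results exactly
comparable across cells — two identical rating columns receive bit-equal
results, and a matrix diagonal reproduces the standalone evaluation
exactly — at no statistical cost.

## Variance partitioning

Three models per attribute (space A, space B, concatenation [A, B], same
CV protocol, features re-standardized jointly, same λ grid) are scored on
the test set by R² = 1 − SSE/SST. SST is taken about the *test-sample*
mean by default (a training-mean baseline is available); out-of-sample R²
and the derived components may be negative and are reported as-is,
because preserving the identity `unique_A + unique_B + shared = R²_joint`
outranks cosmetic truncation. The identity is asserted to machine
precision in every bootstrap draw.

Bootstrap: models are fit once; test faces are resampled and the three R²
recomputed per draw. A component's p-value is one-sided against zero,
oriented by the sign of the point estimate (the "different from zero"
question); pairwise component differences are tested the same way. The
in-sample OLS dominance `R²_joint ≥ max(R²_A, R²_B)` is asserted only in
sample — it can legitimately fail out of sample and under regularization.

## Cross-prediction and semi-partial analysis

The cross-prediction matrix is rectangular: rows are test attributes
(possibly without a trained model), columns are models sharing one
feature space. The highest-|ρ| model per row is flagged. Summaries
exclude same-attribute cells: mean |ρ| over cross cells, mean per-row
maximum |ρ|, and the fraction of significant cells.

Semi-partial residualization follows the hybrid construction exactly: the
control model's predictions Z are removed from another model's
predictions Y by *ordinary least squares on raw scores*, then the
residuals are *rank*-correlated with the human ratings X ("semi-partial"
because Z is removed from Y only, never from X). A control whose
predictions explain a model's predictions completely (residual spread
below 10⁻⁹ of Y's spread) flags that model degenerate; it is excluded,
not scored. A control with constant predictions is an error — note that a
weight vector scaled toward zero does not approach a no-op control,
because regression on Z removes Z's *direction* regardless of amplitude.
The control minimizing mean residual accuracy is marked as the most
impactful attribute.

## The synthetic-data generator

The generator emulates the latent structure the analyses assume, with
full seed control (same config + seed ⇒ bit-identical worlds):

- **Latents.** Each face has K i.i.d. standard-normal latent scores
  (default K = 3; valid range 2 ≤ K ≤ n_attributes).
- **Ratings.** Attribute a has a loading row l_a on the latents
  (user-supplied or unit-norm random). The mean rating is an affine map
  of l_a·z into the Likert range — centered at the scale midpoint, with
  ±3 theoretical SDs spanning the scale — plus per-face noise of SD
  `rating_noise_sd / sqrt(n_raters)`, then clipped to [1, 7]. Rater
  averaging is analytic (only per-face means are ever modelled);
  clipping-induced distortion is acceptable because evaluation is
  rank-based. Defaults `rating_noise_sd = 1.5` (a realistic single-rater
  Likert SD) and `n_raters = 30` give highly reliable per-face means, as
  real rating databases do.
- **Features.** Each space applies a fixed random linear map (unit-norm
  columns) to the stack of `sqrt(shared_fraction) ×` (gain-weighted
  common latents) and `sqrt(unique_fraction) ×` space-private latents,
  plus i.i.d. noise. Linear generation makes the population
  least-squares weights well-defined (via Cov(X)⁻¹Cov(X, y), recorded as
  `true_weights` on the raw feature scale) for recovery tests. The
  optional per-space `latent_gain` masks individual common dimensions,
  which is how worlds with designed unique/shared rating variance between
  two spaces are built. The three default space profiles (identity-like
  128-d / object-like 26-d / geometry-like 30-d) carry decreasing signal
  fractions and increasing noise, mirroring the accuracy ordering such
  spaces show empirically.
- **Test sets.** Disjoint face identifiers, freshly drawn latents, rater
  noise and feature noise; the latent-to-feature maps stay fixed (the
  "cameras" do not change between datasets). With
  `images_per_identity > 1`, identity groups share one latent score with
  image-specific noise, and an identity map is emitted for the
  identity-aware bootstrap.
- **Style perturbation.** One random unit direction in feature space per
  dataset — a single global style axis, as a uniform manipulation like
  grayscale conversion induces — along which each face moves by an
  independent N(0, `style_perturbation_sd`) amount, attenuated by the
  space's `style_sensitivity`. A per-face magnitude is essential: a
  strictly constant offset would leave ranks, and hence every rank-based
  accuracy, untouched. The robustness studies use
  `style_perturbation_sd = 2` — a perturbation comparable to twice the
  signal scale, i.e., a drastic style change.
- **Landmarks.** A symmetric 68-point template face (iBUG 300-W
  ordering) plus a bilaterally symmetric random shape deformation
  (default SD 3 px) plus left/right asymmetry noise, with a synthetic
  skin-luminance scalar. Zero asymmetry yields exactly mirror-symmetric
  faces.

What the generator does **not** emulate: individual-rater response
styles, nonlinear feature–judgment relationships, race and context
effects, or actual image content. Passing tests therefore certify the
statistical machinery and its calibration on worlds with known ground
truth — not that any particular feature space predicts real human
judgments.

## Geometry features

Faces are canonicalized before measurement (rotated about the centroid so
the pupil line — eye-landmark centroids — is horizontal; no reflection),
making all 30 features invariant to in-plane rotation and translation;
ratio features are additionally scale-invariant. Each feature has one
documented formula in `FEATURE_REGISTRY`; the names follow the
social-perception literature, but several (face shape, nose shape,
cheekbone prominence, heartshapeness) have no canonical formula — the
registry entries are this package's definitions, centralized so they can
be revised without touching the pipeline. Skin luminance is consumed as a
precomputed scalar from an upstream segmentation mask; no image parsing
is performed. Degenerate geometry (zero face width, coincident pupils)
raises an error naming the offending measure.

## PCA feature spaces

Bases are fitted on an independent reference face set (centered, not
scaled — activations share units within a layer) and projection always
uses the basis mean, so held-out faces are treated identically to
reference faces and test-set variance never leaks into the basis.
Component-count selection scans a candidate range, scoring each count by
the cross-validated accuracy of the resulting models *on training ratings
only* (error-based λ selection, accuracy summarized as the mean
validation-fold Spearman ρ across attributes); ties go to fewer
components.

## Problem sizes in tests and acceptance runs

The shipped checks use worlds of 120–500 training faces, 60–1,000 test
faces, 2–14 attributes, and resampling sizes of 150–1,000 draws, with
Monte-Carlo repetitions of 25–100 seeds per directional claim; these
sizes give stable outcomes for every property tested while keeping the
whole suite in the tens of seconds. The full-scale protocol
(10,000/10,000/2,000) is exercised through the same code paths and
remains available via `FitConfig`/`RunConfig` and the CLI `--full-scale`
flag.

## Known limitations

- Linear models only (no elastic net, no nonlinear link); the generator
  is correspondingly linear, so model-misspecification behavior is out of
  scope.
- The semi-partial analysis controls one attribute at a time; no
  multi-attribute partialing.
- Variance partitioning is pairwise; no three-way decomposition.
- The bundled landmark template is a stylized frontal face; it exercises
  the geometry formulas but is not anthropometrically calibrated.
- Permutation p-values are plain proportions by default and can be
  exactly zero; use the smoothed variant where downstream procedures
  require strictly positive p-values.
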
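# facejudge

Predicting — and auditing — human social judgments from face-derived
feature spaces.

People form rapid, consensual impressions of faces (trustworthy, dominant,
attractive, ...). These judgments can be modelled surprisingly well by
linear regression from generic numeric representations of the face: an
identity embedding from a face-recognition network, PCA-reduced
convolutional activations from an object-recognition network, or a few
dozen landmark-derived geometric measures. Because social judgments
themselves occupy a low-dimensional latent space (a handful of dimensions
carry most of the rating variance across many named attributes), such
models raise two auditing questions that are as important as raw accuracy:
*which feature space carries which share of the explainable variance*, and
*how specific is a model really* — does a "trustworthy" model predict
trustworthiness, or just the shared valence dimension?

`facejudge` implements the full modelling-and-auditing loop for
researchers in social perception and face psychometrics:

- **Model fitting** (`facejudge.model_fitting`) — per-attribute ridge,
  LASSO or OLS models `ŷ = Xw + b` mapping a feature table (faces ×
  features) to mean Likert ratings. The regularization strength λ is
  selected by repeated random 80/20 splits of the training faces (default
  2,000 iterations, 30 log-spaced grid values, ridge over [1, 10⁵], LASSO
  over [0.01, 100]), minimizing mean validation MSE, then refitting on all
  faces. Features are z-scored with training-fold statistics inside every
  split.
- **Evaluation** (`facejudge.evaluation`) — out-of-sample accuracy as
  Spearman's ρ between predicted and human ratings; bootstrap mean ± SD
  over resampled test faces (identity-aware for multi-image "ambient"
  sets: one image per identity per draw); a permutation null with the
  95th-percentile chance threshold and one-sided p-values;
  Benjamini–Hochberg FDR across attributes. Antonym attributes are
  predicted by negating a model's weights.
- **Variance partitioning** (`facejudge.variance_partitioning`) — for two
  spaces A and B, models on A, B, and [A, B] give out-of-sample R², and
  R²_uA = R²_{A∪B} − R²_B, R²_uB = R²_{A∪B} − R²_A,
  R²_{A∩B} = R²_A + R²_B − R²_{A∪B}, with bootstrap uncertainty.
- **Specificity audits** (`facejudge.cross_prediction`) — the full matrix
  of (model trained on attribute *i*) × (ratings of attribute *j*), with
  per-cell significance; semi-partial residual analysis (regress model
  predictions Y on a control model's predictions Z, rank-correlate the
  residuals with human ratings X) to locate the attribute carrying the
  shared signal; and dataset-level summaries (mean |ρ|, mean per-row max
  |ρ|, fraction of significant cross-predictions).
- **Feature spaces** (`facejudge.feature_spaces`) — ingestion of any
  per-face feature CSV, PCA reduction on an independent reference face
  set, and predictive selection of the component count.
- **Geometry features** (`facejudge.geometry_features`) — 30 interpretable
  measures (fWHR, eye size, face roundness, ...) from 68-point iBUG
  300-W landmarks, with a documented formula registry.
- **Synthetic data** (`facejudge.synthetic_data`) — seeded generator of
  rating tables, feature spaces with controlled shared/unique signal,
  landmark sets, out-of-sample test sets with disjoint faces and fresh
  raters, multi-image identity sets, and a style perturbation that
  contaminates feature spaces differentially — so every stage is testable
  end to end with known ground truth.

## Worked example

Fit ridge models on a synthetic training set of 183 faces and score them
on 60 novel faces rated by fresh raters:

```python
from facejudge.synthetic_data import SyntheticWorldConfig, generate_world
from facejudge.model_fitting import FitConfig, fit_all_attributes
from facejudge.evaluation import evaluate_models

config = SyntheticWorldConfig(n_latent=2, n_train_faces=183, n_test_faces=60,
                              n_attributes=6, seed=0)
world = generate_world(config)

fit_config = FitConfig(method="ridge", n_cv_iterations=200, seed=0)
models = fit_all_attributes(world.train_features["identity-like"],
                            world.train_ratings, fit_config)

test = world.test_sets[0]
results = evaluate_models(
    models, test.ratings, test.features["identity-like"],
    [(a, a, False) for a in world.train_ratings.attributes],
    n_boot=1000, n_perm=1000, seed=0,
)
for r in results:
    print(f"{r.test_attribute}: rho = {r.mean_rho:.3f} +/- {r.boot_sd:.3f}  "
          f"chance = {r.chance_threshold:.3f}  q = {r.q_fdr:.4f}")
```

Output:

```
attr_01: rho = 0.921 +/- 0.026  chance = 0.216  q = 0.0000
attr_02: rho = 0.931 +/- 0.027  chance = 0.218  q = 0.0000
attr_03: rho = 0.952 +/- 0.015  chance = 0.228  q = 0.0000
attr_04: rho = 0.911 +/- 0.028  chance = 0.210  q = 0.0000
attr_05: rho = 0.937 +/- 0.021  chance = 0.219  q = 0.0000
attr_06: rho = 0.948 +/- 0.018  chance = 0.215  q = 0.0000
```

Each line is one social attribute: the bootstrap-mean rank correlation
between predicted and human ratings on novel faces (± bootstrap SD), the
95th-percentile chance threshold from the permutation null, and the
FDR-corrected p-value. Accuracies here are high because the default
synthetic world is low-noise by design; the `identity-like` space is
generated with the largest share of judgment-relevant signal, followed by
`object-like` and `geometry-like`, mirroring the accuracy ordering such
models show on real face databases.

The same workflow runs from the shell:

```bash
facejudge run --seed 0 --out demo_run           # full pipeline, demo scale
facejudge run --seed 0 --full-scale            # 10k bootstrap / 10k permutation / 2k CV
facejudge geometry --n-faces 50 --out geom.csv  # landmark-derived features only
```

`facejudge run` writes rating/feature CSVs, fitted models (JSON),
evaluation and variance-partitioning tables, the cross-prediction matrix
with semi-partial summaries, and a manifest with per-artifact SHA-256
checksums; re-running with the same seed reproduces every checksum.

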
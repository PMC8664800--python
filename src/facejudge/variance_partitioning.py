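"""Unique and shared out-of-sample explained variance between feature spaces.

For one attribute and two feature spaces A and B, three models are fit on
the training faces with the same cross-validated protocol: on A alone, on
B alone, and on the concatenation of both. Out-of-sample R^2 of the three
models then decomposes:

    unique_A = R2_joint - R2_B
    unique_B = R2_joint - R2_A
    shared   = R2_A + R2_B - R2_joint

so unique_A + unique_B + shared = R2_joint identically. Out-of-sample R^2
values (and hence components) can be negative; they are reported as-is
because preserving the identity outranks cosmetic truncation. Uncertainty
comes from resampling test faces with replacement with the fitted models
held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from facejudge.model_fitting import FitConfig, FittedModel, fit_attribute_model, predict
from facejudge.tables import FeatureTable, RatingTable, concat_feature_tables

__all__ = ["VariancePartition", "partition_variance", "bootstrap_partition", "r2_out_of_sample"]

_COMPONENTS = ("unique_a", "unique_b", "shared")


@dataclass
class VariancePartition:
    attribute: str
    space_a: str
    space_b: str
    r2_a: float
    r2_b: float
    r2_joint: float
    unique_a: float
    unique_b: float
    shared: float
    boot_sd: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    p_diff: dict[tuple[str, str], float] = field(default_factory=dict)
    n_boot: int = 0


def r2_out_of_sample(actual: np.ndarray, predicted: np.ndarray, baseline_mean: float | None = None) -> float:
    """Coefficient of determination 1 - SSE/SST.

    SST is taken about the test-sample mean by default; pass a training
    mean via ``baseline_mean`` to use that instead.
    """
    actual = np.asarray(actual, float)
    predicted = np.asarray(predicted, float)
    mean = actual.mean() if baseline_mean is None else baseline_mean
    sst = float(((actual - mean) ** 2).sum())
    if sst == 0:
        raise ValueError("test ratings are constant; R^2 undefined")
    sse = float(((actual - predicted) ** 2).sum())
    return 1.0 - sse / sst


def _derive(r2_a: float, r2_b: float, r2_joint: float) -> tuple[float, float, float]:
    unique_a = r2_joint - r2_b
    unique_b = r2_joint - r2_a
    shared = r2_a + r2_b - r2_joint
    # the identity is exact by construction; guard against regressions
    assert abs((unique_a + unique_b + shared) - r2_joint) <= 1e-12 * max(1.0, abs(r2_joint))
    return unique_a, unique_b, shared


def _fit_three(
    ratings_train: RatingTable,
    feats_a: FeatureTable,
    feats_b: FeatureTable,
    attribute: str,
    fit_config: FitConfig,
) -> tuple[FittedModel, FittedModel, FittedModel]:
    if feats_a.space_name == feats_b.space_name:
        raise ValueError("the two feature spaces must be distinct")
    joint_train = concat_feature_tables(feats_a, feats_b)
    model_a = fit_attribute_model(feats_a, ratings_train, attribute, fit_config)
    model_b = fit_attribute_model(feats_b, ratings_train, attribute, fit_config)
    model_j = fit_attribute_model(joint_train, ratings_train, attribute, fit_config)
    return model_a, model_b, model_j


def _test_predictions(
    models: tuple[FittedModel, FittedModel, FittedModel],
    ratings_test: RatingTable,
    test_a: FeatureTable,
    test_b: FeatureTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    test_a = test_a.reindex(ratings_test.face_ids)
    test_b = test_b.reindex(ratings_test.face_ids)
    joint_test = concat_feature_tables(test_a, test_b)
    model_a, model_b, model_j = models
    return (
        ratings_test.column(models[0].attribute),
        predict(model_a, test_a),
        predict(model_b, test_b),
        predict(model_j, joint_test),
    )


def partition_variance(
    ratings_train: RatingTable,
    feats_a: FeatureTable,
    feats_b: FeatureTable,
    ratings_test: RatingTable,
    test_a: FeatureTable,
    test_b: FeatureTable,
    attribute: str,
    fit_config: FitConfig,
    baseline: str = "test_mean",
) -> VariancePartition:
    """Point estimate of the unique/shared decomposition for one attribute."""
    models = _fit_three(ratings_train, feats_a, feats_b, attribute, fit_config)
    actual, pred_a, pred_b, pred_j = _test_predictions(models, ratings_test, test_a, test_b)
    base = None if baseline == "test_mean" else float(ratings_train.column(attribute).mean())
    r2_a = r2_out_of_sample(actual, pred_a, base)
    r2_b = r2_out_of_sample(actual, pred_b, base)
    r2_j = r2_out_of_sample(actual, pred_j, base)
    ua, ub, sh = _derive(r2_a, r2_b, r2_j)
    return VariancePartition(
        attribute, feats_a.space_name, feats_b.space_name, r2_a, r2_b, r2_j, ua, ub, sh
    )


def bootstrap_partition(
    ratings_train: RatingTable,
    feats_a: FeatureTable,
    feats_b: FeatureTable,
    ratings_test: RatingTable,
    test_a: FeatureTable,
    test_b: FeatureTable,
    attribute: str,
    fit_config: FitConfig,
    n_boot: int = 10_000,
    seed: int = 0,
    baseline: str = "test_mean",
) -> VariancePartition:
    """Partition with bootstrap SDs and one-sided sign-oriented p-values.

    Models are fitted once on the training faces; each bootstrap draw
    resamples test faces with replacement and recomputes the three R^2
    values and the derived components. A component's p is the proportion
    of draws on the opposite side of zero from its point estimate (the
    "different from zero" test); pairwise difference p-values are
    analogous. Degenerate (constant-rating) resamples are skipped.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    part = partition_variance(
        ratings_train, feats_a, feats_b, ratings_test, test_a, test_b, attribute, fit_config, baseline
    )
    models = _fit_three(ratings_train, feats_a, feats_b, attribute, fit_config)
    actual, pred_a, pred_b, pred_j = _test_predictions(models, ratings_test, test_a, test_b)
    base = None if baseline == "test_mean" else float(ratings_train.column(attribute).mean())

    rng = np.random.default_rng(seed)
    n = actual.size
    draws = {name: [] for name in ("r2_a", "r2_b", "r2_joint", *_COMPONENTS)}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a = actual[idx]
        if np.ptp(a) == 0:
            continue
        r2a = r2_out_of_sample(a, pred_a[idx], base)
        r2b = r2_out_of_sample(a, pred_b[idx], base)
        r2j = r2_out_of_sample(a, pred_j[idx], base)
        ua, ub, sh = _derive(r2a, r2b, r2j)
        for name, val in zip(draws, (r2a, r2b, r2j, ua, ub, sh)):
            draws[name].append(val)
    if not draws["r2_a"]:
        raise ValueError("all bootstrap resamples were degenerate (constant ratings)")
    arrays = {k: np.asarray(v) for k, v in draws.items()}

    estimates = {
        "r2_a": part.r2_a,
        "r2_b": part.r2_b,
        "r2_joint": part.r2_joint,
        "unique_a": part.unique_a,
        "unique_b": part.unique_b,
        "shared": part.shared,
    }
    part.boot_sd = {k: float(v.std(ddof=0)) for k, v in arrays.items()}
    part.p = {
        k: float(
            (arrays[k] <= 0).mean() if estimates[k] >= 0 else (arrays[k] >= 0).mean()
        )
        for k in _COMPONENTS
    }
    for i, c1 in enumerate(_COMPONENTS):
        for c2 in _COMPONENTS[i + 1 :]:
            diff = arrays[c1] - arrays[c2]
            point = estimates[c1] - estimates[c2]
            part.p_diff[(c1, c2)] = float(
                (diff <= 0).mean() if point >= 0 else (diff >= 0).mean()
            )
    part.n_boot = len(arrays["r2_a"])
    return part
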
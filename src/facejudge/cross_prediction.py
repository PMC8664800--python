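"""Prediction specificity audits: cross-prediction and semi-partial residuals.

A model trained on one attribute (say, trustworthy) often predicts human
ratings of *other* attributes nearly as well — a direct consequence of the
low-dimensional latent structure of social judgments. The cross-prediction
matrix quantifies this: every (test attribute, trained model) pair gets a
bootstrap Spearman accuracy with permutation significance, FDR-corrected
across the whole matrix. The semi-partial analysis asks which attribute
carries the shared signal: the control model's predictions Z are partialed
out of each other model's predictions Y by ordinary least squares, and the
residuals are rank-correlated with the human ratings X. If one attribute's
model routes most of the shared variance, controlling it collapses the
residual cross-predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from facejudge.evaluation import (
    AccuracyResult,
    bootstrap_accuracy,
    fdr_adjust,
    permutation_null,
)
from facejudge.model_fitting import FittedModel, predict
from facejudge.tables import FeatureTable, RatingTable

__all__ = [
    "CrossPredictionMatrix",
    "SemiPartialResult",
    "cross_prediction_matrix",
    "semi_partial_residual_matrix",
    "cross_prediction_summaries",
]


@dataclass
class CrossPredictionMatrix:
    model_attributes: list[str]
    test_attributes: list[str]
    cells: dict[tuple[str, str], AccuracyResult]  # (test attr, model attr)
    row_argmax: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test_attribute": t,
                "model_attribute": m,
                "mean_rho": c.mean_rho,
                "boot_sd": c.boot_sd,
                "chance_threshold": c.chance_threshold,
                "p_perm": c.p_perm,
                "q_fdr": c.q_fdr,
                "significant": c.significant,
                "row_max": self.row_argmax.get(t) == m,
            }
            for (t, m), c in self.cells.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class SemiPartialResult:
    control_attribute: str
    matrix: CrossPredictionMatrix
    degenerate_models: list[str]
    mean_abs_rho: float
    mean_row_max_abs_rho: float
    frac_significant: float


def _check_shared_space(models: Mapping[str, FittedModel], features: FeatureTable) -> None:
    spaces = {m.space_name for m in models.values()}
    if len(spaces) != 1:
        raise ValueError(f"models span multiple feature spaces: {sorted(spaces)}")
    if features.space_name not in spaces:
        raise ValueError(
            f"test features are {features.space_name!r} but models were fitted on "
            f"{spaces.pop()!r}"
        )


def _score_cells(
    predictions: Mapping[str, np.ndarray],
    test_ratings: RatingTable,
    test_attributes: Sequence[str],
    identity_map: Mapping[str, str] | None,
    n_boot: int,
    n_perm: int,
    alpha: float,
    seed: int,
) -> dict[tuple[str, str], AccuracyResult]:
    cells: dict[tuple[str, str], AccuracyResult] = {}
    # one shared resampling stream across cells (same seed everywhere):
    # duplicated targets then yield exactly equal cells, and the diagonal
    # reproduces the evaluation module's result for the same seed
    for test_attr in test_attributes:
        actual = test_ratings.column(test_attr)
        for model_attr, pred in predictions.items():
            mean_rho, boot_sd, n_deg = bootstrap_accuracy(
                pred,
                actual,
                identity_map=identity_map,
                n_boot=n_boot,
                seed=seed,
                face_ids=test_ratings.face_ids,
            )
            threshold, p, _ = permutation_null(pred, actual, n_perm=n_perm, seed=seed + 1)
            cells[(test_attr, model_attr)] = AccuracyResult(
                model_attribute=model_attr,
                test_attribute=test_attr,
                mean_rho=mean_rho,
                boot_sd=boot_sd,
                chance_threshold=threshold,
                p_perm=p,
                n_boot=n_boot,
                n_perm=n_perm,
                n_degenerate=n_deg,
            )
    qs = fdr_adjust([c.p_perm for c in cells.values()])
    for c, q in zip(cells.values(), qs):
        c.q_fdr = float(q)
        c.significant = bool(q < alpha)
    return cells


def _finalize_matrix(
    cells: dict[tuple[str, str], AccuracyResult],
    model_attributes: list[str],
    test_attributes: list[str],
) -> CrossPredictionMatrix:
    matrix = CrossPredictionMatrix(model_attributes, test_attributes, cells)
    for t in test_attributes:
        row = [(m, cells[(t, m)].mean_rho) for m in model_attributes if (t, m) in cells]
        if row:
            matrix.row_argmax[t] = max(row, key=lambda kv: abs(kv[1]))[0]
    return matrix


def cross_prediction_matrix(
    models: Mapping[str, FittedModel],
    test_ratings: RatingTable,
    test_features: FeatureTable,
    identity_map: Mapping[str, str] | None = None,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> CrossPredictionMatrix:
    """Accuracy of every trained model against every test attribute.

    Rows are test attributes (which may include attributes with no trained
    model — the matrix is rectangular); columns are trained models, all
    sharing one feature space. FDR family = all cells jointly. The
    highest-|rho| model per row is flagged.
    """
    _check_shared_space(models, test_features)
    feats = test_features.reindex(test_ratings.face_ids)
    predictions = {attr: predict(m, feats) for attr, m in models.items()}
    cells = _score_cells(
        predictions, test_ratings, test_ratings.attributes, identity_map, n_boot, n_perm, alpha, seed
    )
    return _finalize_matrix(cells, list(models), list(test_ratings.attributes))


def residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of the simple least-squares regression of y on z."""
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    if np.ptp(z) == 0:
        raise ValueError("control predictions are constant; cannot residualize")
    zc = z - z.mean()
    beta = float(zc @ (y - y.mean()) / (zc @ zc))
    return y - (y.mean() + beta * zc)


def semi_partial_residual_matrix(
    models: Mapping[str, FittedModel],
    test_ratings: RatingTable,
    test_features: FeatureTable,
    control_attribute: str,
    identity_map: Mapping[str, str] | None = None,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    degenerate_tol: float = 1e-9,
) -> SemiPartialResult:
    """Cross-prediction matrix after partialing the control model out.

    For each non-control model, its predictions Y are regressed on the
    control model's predictions Z by ordinary least squares on raw scores;
    the residuals are then rank-correlated with each test attribute's
    human ratings X (the semi-partial construction: Z is removed from Y
    only, not from X). Models whose predictions are explained away by Z
    (residual spread below ``degenerate_tol`` of Y's spread) are flagged
    degenerate and excluded, not scored.
    """
    if control_attribute not in models:
        raise KeyError(f"no fitted model for control attribute {control_attribute!r}")
    others = [a for a in models if a != control_attribute]
    if len(others) < 2:
        raise ValueError("semi-partial analysis needs at least 2 non-control models")
    _check_shared_space(models, test_features)
    feats = test_features.reindex(test_ratings.face_ids)
    z = predict(models[control_attribute], feats)

    residuals: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for attr in others:
        y = predict(models[attr], feats)
        resid = residualize(y, z)
        if np.ptp(resid) <= degenerate_tol * max(np.ptp(y), 1.0):
            degenerate.append(attr)
        else:
            residuals[attr] = resid
    if not residuals:
        raise ValueError("all non-control models are degenerate after residualization")

    cells = _score_cells(
        residuals, test_ratings, test_ratings.attributes, identity_map, n_boot, n_perm, alpha, seed
    )
    matrix = _finalize_matrix(cells, list(residuals), list(test_ratings.attributes))
    mean_abs, mean_row_max, frac_sig = _summarize(matrix)
    return SemiPartialResult(
        control_attribute=control_attribute,
        matrix=matrix,
        degenerate_models=degenerate,
        mean_abs_rho=mean_abs,
        mean_row_max_abs_rho=mean_row_max,
        frac_significant=frac_sig,
    )


def _summarize(matrix: CrossPredictionMatrix) -> tuple[float, float, float]:
    """Mean |rho|, mean per-row max |rho|, significant fraction.

    Same-attribute (self-prediction) cells are excluded: the summaries
    describe cross-predictions only.
    """
    cross = {
        (t, m): c for (t, m), c in matrix.cells.items() if t != m
    }
    if not cross:
        return float("nan"), float("nan"), float("nan")
    abs_rho = np.asarray([abs(c.mean_rho) for c in cross.values()])
    row_max = []
    for t in matrix.test_attributes:
        vals = [abs(c.mean_rho) for (tt, m), c in cross.items() if tt == t]
        if vals:
            row_max.append(max(vals))
    frac_sig = float(np.mean([c.significant for c in cross.values()]))
    return float(abs_rho.mean()), float(np.mean(row_max)), frac_sig


def cross_prediction_summaries(
    matrix: CrossPredictionMatrix,
    residual_results: Sequence[SemiPartialResult] = (),
) -> pd.DataFrame:
    """Dataset-level specificity summaries, per control attribute.

    One row per control ("none" = the raw matrix): mean |rho| across
    cross-prediction cells, mean per-row maximum |rho|, and the fraction
    of significant cells. The control minimizing the mean residual
    accuracy (the most impactful attribute) is marked.
    """
    if not matrix.cells:
        raise ValueError("cross-prediction matrix is empty")
    rows = []
    mean_abs, mean_row_max, frac_sig = _summarize(matrix)
    rows.append(
        {
            "control": "none",
            "mean_abs_rho": mean_abs,
            "mean_row_max_abs_rho": mean_row_max,
            "frac_significant": frac_sig,
        }
    )
    for res in residual_results:
        rows.append(
            {
                "control": res.control_attribute,
                "mean_abs_rho": res.mean_abs_rho,
                "mean_row_max_abs_rho": res.mean_row_max_abs_rho,
                "frac_significant": res.frac_significant,
            }
        )
    df = pd.DataFrame(rows)
    controls = df[df["control"] != "none"]
    df["most_impactful_control"] = False
    if len(controls):
        idx = controls["mean_abs_rho"].idxmin()
        df.loc[idx, "most_impactful_control"] = True
    return df
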
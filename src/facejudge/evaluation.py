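"""Out-of-sample scoring: bootstrap Spearman accuracy, permutation nulls, FDR.

Prediction accuracy is Spearman's rank correlation between model-predicted
and human mean ratings, chosen because test datasets use heterogeneous
rating scales and rank order is the stable quantity. Uncertainty comes from
resampling test faces with replacement (identity-aware for multi-image
"ambient" sets: one image per identity per draw); chance level comes from
shuffling ratings across faces (95th percentile of the null), with
Benjamini-Hochberg control across the evaluated family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from facejudge.model_fitting import FittedModel, predict
from facejudge.tables import FeatureTable, RatingTable

__all__ = [
    "AccuracyResult",
    "spearman",
    "bootstrap_accuracy",
    "permutation_null",
    "fdr_adjust",
    "evaluate_models",
]


@dataclass
class AccuracyResult:
    """Bootstrap + permutation summary for one (model, test attribute) pair."""

    model_attribute: str
    test_attribute: str
    mean_rho: float
    boot_sd: float
    chance_threshold: float
    p_perm: float
    q_fdr: float = float("nan")
    significant: bool = False
    n_boot: int = 0
    n_perm: int = 0
    n_degenerate: int = 0


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < 3:
        raise ValueError(f"{name} must have length >= 3")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    if np.ptp(v) == 0:
        raise ValueError(f"{name} is constant; Spearman correlation undefined")
    return v


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive their average rank. Raises on constant input, naming the
    offending vector.
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    rx = rankdata(xv)
    ry = rankdata(yv)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _rowwise_spearman(pred_rows: np.ndarray, act_rows: np.ndarray) -> np.ndarray:
    """Spearman per row of two equal-shape 2-D arrays; NaN for constant rows."""
    rx = rankdata(pred_rows, axis=1)
    ry = rankdata(act_rows, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    sx = np.einsum("ij,ij->i", rx, rx)
    sy = np.einsum("ij,ij->i", ry, ry)
    denom = np.sqrt(sx * sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("ij,ij->i", rx, ry) / denom
    rho[denom == 0] = np.nan
    return rho


def bootstrap_accuracy(
    predicted,
    actual,
    identity_map: Mapping[str, str] | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    face_ids: Sequence[str] | None = None,
) -> tuple[float, float, int]:
    """Mean and SD of Spearman accuracy over resamples of test faces.

    Each iteration resamples faces with replacement and recomputes the
    correlation. When ``identity_map`` maps faces to identities (ambient
    multi-image sets), one face per identity is drawn uniformly first and
    the resulting identities are then resampled with replacement, so no
    identity dominates a draw. Degenerate (constant) resamples are skipped
    and counted.

    Returns
    -------
    (mean_rho, boot_sd, n_degenerate)
    """
    pv = _as_vector(predicted, "predicted")
    av = _as_vector(actual, "actual")
    if pv.size != av.size:
        raise ValueError("predicted and actual must have equal length")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = pv.size

    if identity_map is not None:
        if face_ids is None:
            raise ValueError("face_ids are required with an identity_map")
        ids = [identity_map[f] for f in face_ids]
        groups: dict[str, list[int]] = {}
        for i, ident in enumerate(ids):
            groups.setdefault(ident, []).append(i)
        members = list(groups.values())
        k = len(members)
        # per iteration: pick one image per identity, then resample identities
        choice = np.empty((n_boot, k), dtype=int)
        for j, mem in enumerate(members):
            mem_arr = np.asarray(mem)
            choice[:, j] = mem_arr[rng.integers(0, len(mem_arr), size=n_boot)]
        ident_idx = rng.integers(0, k, size=(n_boot, k))
        idx = np.take_along_axis(choice, ident_idx, axis=1)
    else:
        idx = rng.integers(0, n, size=(n_boot, n))

    rho = _rowwise_spearman(pv[idx], av[idx])
    valid = np.isfinite(rho)
    n_degenerate = int((~valid).sum())
    if not valid.any():
        raise ValueError("all bootstrap resamples were degenerate (constant)")
    rho = rho[valid]
    return float(rho.mean()), float(rho.std(ddof=0)), n_degenerate


def permutation_null(
    predicted,
    actual,
    n_perm: int = 10_000,
    seed: int = 0,
    smoothed: bool = False,
    exhaustive: bool = False,
) -> tuple[float, float, np.ndarray]:
    """Empirical null of Spearman accuracy under shuffled ratings.

    Shuffles ``actual`` across faces ``n_perm`` times and recomputes the
    correlation against fixed predictions. Returns the 95th percentile of
    the null (the chance threshold), the one-sided p-value (proportion of
    null draws >= the observed correlation; ``smoothed`` adds the +1/(n+1)
    correction), and the null sample itself. With ``exhaustive=True`` all
    n! orderings are enumerated instead of sampled (small n only; the null
    and p-value are then exact and ``n_perm``/``seed`` are ignored).
    """
    pv = _as_vector(predicted, "predicted")
    av = _as_vector(actual, "actual")
    if pv.size != av.size:
        raise ValueError("predicted and actual must have equal length")
    n = pv.size
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to n <= 8")
        from itertools import permutations

        perm = np.asarray(list(permutations(range(n))))
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
    null = _rowwise_spearman(np.broadcast_to(pv, (perm.shape[0], n)), av[perm])
    null = null[np.isfinite(null)]
    observed = spearman(pv, av)
    threshold = float(np.percentile(null, 95))
    ge = int((null >= observed).sum())
    if smoothed:
        p = (ge + 1) / (null.size + 1)
    else:
        p = ge / null.size
    return threshold, float(p), null


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def evaluate_models(
    models: Mapping[str, FittedModel],
    test_ratings: RatingTable,
    test_features: FeatureTable,
    attribute_mapping: Sequence[tuple[str, str, bool]],
    identity_map: Mapping[str, str] | None = None,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[AccuracyResult]:
    """Score each (model attribute, test attribute, antonym flag) pair.

    Antonym-flagged pairs negate the model weights before predicting
    (e.g., a "dominant" model predicting "submissive" ratings). FDR is
    applied across the evaluated family at level ``alpha``.
    """
    feats = test_features.reindex(test_ratings.face_ids)
    results: list[AccuracyResult] = []
    # one shared resampling stream across pairs: identical draws of test
    # faces for every pair make results exactly comparable across cells
    for model_attr, test_attr, antonym in attribute_mapping:
        if model_attr not in models:
            raise KeyError(f"no fitted model for attribute {model_attr!r}")
        model = models[model_attr]
        pred = predict(model, feats, flip_sign=antonym)
        actual = test_ratings.column(test_attr)
        mean_rho, boot_sd, n_deg = bootstrap_accuracy(
            pred,
            actual,
            identity_map=identity_map,
            n_boot=n_boot,
            seed=seed,
            face_ids=test_ratings.face_ids,
        )
        threshold, p, _ = permutation_null(pred, actual, n_perm=n_perm, seed=seed + 1)
        results.append(
            AccuracyResult(
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
        )
    qs = fdr_adjust([r.p_perm for r in results])
    for r, q in zip(results, qs):
        r.q_fdr = float(q)
        r.significant = bool(q < alpha)
    return results
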
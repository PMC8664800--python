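"""Named feature spaces: ingestion, PCA reduction, component-count selection.

High-dimensional spaces (e.g., flattened convolutional activations) are
reduced by principal components fitted on an independent reference face
set, so test-set variance never leaks into the basis. The component count
is selected by cross-validated prediction accuracy on the training
ratings alone, scanning a candidate range and keeping the count with the
best mean accuracy across attributes (ties go to fewer components).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from facejudge.model_fitting import FitConfig, cross_validated_accuracy
from facejudge.tables import FeatureTable, RatingTable

__all__ = ["PCBasis", "fit_pca_basis", "project", "select_num_components"]


@dataclass
class PCBasis:
    """Orthonormal principal-component basis with its centering mean."""

    mean_vector: np.ndarray
    components: np.ndarray  # (n_components, n_features), orthonormal rows
    explained_variance: np.ndarray
    fitted_on: str

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.components.shape[0]), atol=1e-8):
            raise ValueError("PC basis rows are not orthonormal")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean_vector": self.mean_vector.tolist(),
                "components": self.components.tolist(),
                "explained_variance": self.explained_variance.tolist(),
                "fitted_on": self.fitted_on,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PCBasis":
        d = json.loads(text)
        return cls(
            np.asarray(d["mean_vector"], float),
            np.asarray(d["components"], float),
            np.asarray(d["explained_variance"], float),
            d["fitted_on"],
        )


def fit_pca_basis(reference: FeatureTable, n_components: int) -> PCBasis:
    """PCA basis from a centered reference set, ordered by explained variance."""
    n, p = reference.matrix.shape
    limit = min(n - 1, p)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components must lie in [1, {limit}] for a {n} x {p} reference set"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(reference.matrix)
    return PCBasis(
        mean_vector=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        fitted_on=reference.space_name,
    )


def project(features: FeatureTable, basis: PCBasis) -> FeatureTable:
    """Project faces onto the basis; centering uses the basis mean.

    The projected set's own mean plays no role, so held-out faces are
    projected identically to reference faces.
    """
    if features.matrix.shape[1] != basis.components.shape[1]:
        raise ValueError(
            f"dimension mismatch: features have {features.matrix.shape[1]} columns, "
            f"basis expects {basis.components.shape[1]}"
        )
    scores = (features.matrix - basis.mean_vector) @ basis.components.T
    cols = [f"pc_{i+1:03d}" for i in range(basis.n_components)]
    return FeatureTable(
        f"{features.space_name}-pca",
        pd.DataFrame(scores, index=features.features.index, columns=cols),
    )


def select_num_components(
    reference: FeatureTable,
    train_ratings: RatingTable,
    train_features: FeatureTable,
    scan_min: int,
    scan_max: int,
    step: int = 1,
    fit_config: FitConfig | None = None,
) -> int:
    """Component count maximizing mean cross-validated accuracy.

    For each candidate count the training features are projected onto the
    reference-set basis and per-attribute models are scored by the same
    cross-validated protocol as the main fit (error-based regularization
    selection, accuracy summarized as mean validation Spearman across
    attributes). Only training-set ratings are consulted. Ties break
    toward the smaller count.
    """
    if scan_min < 1 or scan_max < scan_min or step < 1:
        raise ValueError("scan range must satisfy 1 <= scan_min <= scan_max, step >= 1")
    if fit_config is None:
        fit_config = FitConfig(method="ridge", n_cv_iterations=100)
    candidates = list(range(scan_min, scan_max + 1, step))
    basis = fit_pca_basis(reference, max(candidates))
    scores_full = project(train_features, basis)

    best_count, best_acc = candidates[0], -np.inf
    for count in candidates:
        sub = FeatureTable(
            scores_full.space_name, scores_full.features.iloc[:, :count]
        )
        acc = cross_validated_accuracy(sub, train_ratings, fit_config)
        mean_acc = float(np.mean(list(acc.values())))
        if mean_acc > best_acc + 1e-12:  # strict improvement: ties keep fewer PCs
            best_acc, best_count = mean_acc, count
    return best_count
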
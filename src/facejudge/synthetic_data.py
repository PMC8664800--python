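"""Synthetic worlds with the latent structure of social-judgment data.

Human impressions of faces are strongly inter-correlated: a handful of
latent psychological dimensions (valence/trustworthiness, dominance, ...)
account for most rating variance across many named attributes. The
generator reproduces exactly that structure so every downstream stage —
model fitting, out-of-sample evaluation, variance partitioning,
cross-prediction auditing — can be exercised against known ground truth:

* each face has a K-dimensional latent score (i.i.d. standard normal);
* each attribute's mean rating is an affine rescaling of its loading onto
  the latents into the Likert range, plus per-face residual noise of
  ``rating_noise_sd / sqrt(n_raters)`` (rater noise is averaged
  analytically, as only per-face means are ever modelled), then clipped;
* each feature space is a linear image of the latents (the signal shared
  across spaces) plus a linear image of space-private latent factors plus
  i.i.d. feature noise, so true regression weights are well defined;
* test sets use disjoint faces and freshly drawn rater noise;
* an image-style perturbation contaminates feature spaces in proportion to
  their ``style_sensitivity``, emulating low-level image manipulations
  that should not change the judgments themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from facejudge.tables import FeatureTable, RatingTable

__all__ = [
    "FeatureSpaceSpec",
    "SyntheticWorldConfig",
    "SyntheticTestSet",
    "SyntheticWorld",
    "generate_world",
    "apply_style_perturbation",
    "generate_landmarks",
    "random_loadings",
]


@dataclass
class FeatureSpaceSpec:
    """Recipe for one synthetic feature space.

    ``signal_fraction_shared`` weights the latent block common to all
    spaces (the rating-relevant signal); ``signal_fraction_unique`` weights
    a space-private latent block that is uncorrelated with ratings and with
    every other space. ``latent_gain`` optionally masks/weights individual
    shared latent dimensions per space, which lets worlds be built where
    two spaces carry partly disjoint rating-relevant signal (ground truth
    for variance partitioning); default is uniform visibility.
    """

    name: str
    n_features: int
    signal_fraction_shared: float = 0.8
    signal_fraction_unique: float = 0.1
    noise_sd: float = 0.3
    style_sensitivity: float = 0.0
    latent_gain: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for nm in ("signal_fraction_shared", "signal_fraction_unique", "style_sensitivity"):
            v = getattr(self, nm)
            if not 0 <= v <= 1:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.signal_fraction_shared + self.signal_fraction_unique > 1 + 1e-12:
            raise ValueError("signal_fraction_shared + signal_fraction_unique must be <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticWorldConfig:
    """Full recipe for a synthetic study (training set plus test sets)."""

    n_latent: int = 3
    n_train_faces: int = 183
    n_test_faces: int = 60
    n_attributes: int = 14
    attribute_loadings: np.ndarray | None = None
    rating_noise_sd: float = 1.5
    n_raters: int = 30
    likert_min: float = 1.0
    likert_max: float = 7.0
    feature_space_specs: list[FeatureSpaceSpec] = field(
        default_factory=lambda: [
            FeatureSpaceSpec("identity-like", 128, 0.85, 0.10, 0.25, 0.1),
            FeatureSpaceSpec("object-like", 26, 0.65, 0.25, 0.40, 0.9),
            FeatureSpaceSpec("geometry-like", 30, 0.45, 0.35, 0.60, 0.0),
        ]
    )
    images_per_identity: int = 1
    n_test_sets: int = 1
    style_perturbation_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("n_latent", "n_train_faces", "n_test_faces", "n_attributes", "n_raters", "images_per_identity", "n_test_sets"):
            if getattr(self, nm) < 1:
                raise ValueError(f"{nm} must be a positive count")
        if not 2 <= self.n_latent <= self.n_attributes:
            raise ValueError("n_latent must satisfy 2 <= K <= n_attributes")
        if self.rating_noise_sd < 0 or self.style_perturbation_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.likert_min >= self.likert_max:
            raise ValueError("likert_min must be below likert_max")
        if self.attribute_loadings is None:
            self.attribute_loadings = random_loadings(
                self.n_attributes, self.n_latent, seed=self.seed + 1
            )
        self.attribute_loadings = np.asarray(self.attribute_loadings, dtype=float)
        if self.attribute_loadings.shape != (self.n_attributes, self.n_latent):
            raise ValueError(
                f"attribute_loadings must be {self.n_attributes} x {self.n_latent}"
            )
        if np.linalg.matrix_rank(self.attribute_loadings) < self.n_latent:
            raise ValueError(
                "attribute_loadings is rank-deficient: every latent dimension "
                "must load on at least one attribute direction"
            )
        names = [s.name for s in self.feature_space_specs]
        if len(set(names)) != len(names):
            raise ValueError("feature space names must be unique")
        for s in self.feature_space_specs:
            if s.latent_gain is not None and len(s.latent_gain) != self.n_latent:
                raise ValueError(
                    f"latent_gain of space {s.name!r} must have length K={self.n_latent}"
                )

    @property
    def attribute_names(self) -> list[str]:
        return [f"attr_{i+1:02d}" for i in range(self.n_attributes)]


def random_loadings(n_attributes: int, k: int, seed: int = 0) -> np.ndarray:
    """Unit-norm random attribute loadings (rows) on K latent dimensions."""
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_attributes, k))
    return L / np.linalg.norm(L, axis=1, keepdims=True)


@dataclass
class SyntheticTestSet:
    ratings: RatingTable
    features: dict[str, FeatureTable]
    identity_map: dict[str, str] | None
    latent_scores: np.ndarray


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    train_ratings: RatingTable
    train_features: dict[str, FeatureTable]
    test_sets: list[SyntheticTestSet]
    true_weights: dict[str, dict[str, np.ndarray]]
    latent_scores: np.ndarray


def _ratings_from_latents(
    Z: np.ndarray, config: SyntheticWorldConfig, rng: np.random.Generator, face_ids: list[str]
) -> RatingTable:
    L = config.attribute_loadings
    sigma_eff = config.rating_noise_sd / np.sqrt(config.n_raters)
    signal_sd = np.linalg.norm(L, axis=1)
    total_sd = np.sqrt(signal_sd**2 + sigma_eff**2)
    mid = 0.5 * (config.likert_min + config.likert_max)
    span = config.likert_max - config.likert_min
    scale = (span / 6.0) / total_sd  # +-3 theoretical SDs fill the scale
    raw = Z @ L.T + sigma_eff * rng.standard_normal((Z.shape[0], config.n_attributes))
    vals = np.clip(mid + raw * scale, config.likert_min, config.likert_max)
    df = pd.DataFrame(vals, index=face_ids, columns=config.attribute_names)
    return RatingTable(df, config.likert_min, config.likert_max)


def _feature_maps(config: SyntheticWorldConfig) -> dict[str, np.ndarray]:
    """One fixed latent-to-feature map per space (2K x n_features, unit columns)."""
    maps = {}
    for spec in config.feature_space_specs:
        rng = _space_rng_stable(config.seed, "map:" + spec.name)
        A = rng.standard_normal((2 * config.n_latent, spec.n_features))
        maps[spec.name] = A / np.linalg.norm(A, axis=0, keepdims=True)
    return maps


def _space_rng_stable(seed: int, tag: str) -> np.random.Generator:
    # hash() is salted per process; use a stable digest of the tag instead
    digest = np.frombuffer(tag.encode(), dtype=np.uint8).astype(np.uint64)
    h = int((digest * (np.arange(digest.size, dtype=np.uint64) + 1)).sum() % (2**31))
    return np.random.default_rng(np.random.SeedSequence([seed, h]))


def _features_from_latents(
    Z: np.ndarray,
    spec: FeatureSpaceSpec,
    A: np.ndarray,
    config: SyntheticWorldConfig,
    rng: np.random.Generator,
    face_ids: list[str],
) -> FeatureTable:
    n, k = Z.shape
    gain = np.ones(k) if spec.latent_gain is None else np.asarray(spec.latent_gain, float)
    shared = np.sqrt(spec.signal_fraction_shared) * (Z * gain)
    unique = np.sqrt(spec.signal_fraction_unique) * rng.standard_normal((n, k))
    S = np.concatenate([shared, unique], axis=1)
    X = S @ A + spec.noise_sd * rng.standard_normal((n, spec.n_features))
    cols = [f"{spec.name}_f{j+1:03d}" for j in range(spec.n_features)]
    return FeatureTable(spec.name, pd.DataFrame(X, index=face_ids, columns=cols))


def _population_weights(
    spec: FeatureSpaceSpec, A: np.ndarray, config: SyntheticWorldConfig
) -> dict[str, np.ndarray]:
    """Best linear predictor of each attribute from the raw features.

    With S the stacked (shared, unique) latents, Cov(X) = A' D A + sigma^2 I
    and Cov(X, y_a) = A' Cov(S, y_a); only the shared block covaries with
    ratings. Weights are on the raw (unstandardized) feature scale.
    """
    k = config.n_latent
    gain = np.ones(k) if spec.latent_gain is None else np.asarray(spec.latent_gain, float)
    d = np.concatenate(
        [spec.signal_fraction_shared * gain**2, np.full(k, spec.signal_fraction_unique)]
    )
    cov_x = A.T @ (d[:, None] * A) + spec.noise_sd**2 * np.eye(A.shape[1])
    L = config.attribute_loadings
    sigma_eff = config.rating_noise_sd / np.sqrt(config.n_raters)
    total_sd = np.sqrt(np.linalg.norm(L, axis=1) ** 2 + sigma_eff**2)
    span = config.likert_max - config.likert_min
    scale = (span / 6.0) / total_sd
    out = {}
    for a, attr in enumerate(config.attribute_names):
        cov_sy = np.zeros(2 * k)
        cov_sy[:k] = np.sqrt(spec.signal_fraction_shared) * gain * L[a] * scale[a]
        out[attr] = np.linalg.solve(cov_x, A.T @ cov_sy)
    return out


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a full synthetic study from one seeded configuration.

    Training and test faces are disjoint; each test set redraws rater noise
    (fresh raters) and feature noise, while the latent-to-feature maps stay
    fixed (the "cameras" do not change between datasets). With
    ``images_per_identity > 1`` test faces come in identity groups sharing
    one latent score (the same person photographed repeatedly) with
    image-specific rating and feature noise.
    """
    rng = np.random.default_rng(config.seed)
    maps = _feature_maps(config)
    k = config.n_latent

    train_ids = [f"train_{i+1:04d}" for i in range(config.n_train_faces)]
    Z_train = rng.standard_normal((config.n_train_faces, k))
    train_ratings = _ratings_from_latents(Z_train, config, rng, train_ids)
    train_features = {
        spec.name: _features_from_latents(Z_train, spec, maps[spec.name], config, rng, train_ids)
        for spec in config.feature_space_specs
    }

    test_sets = []
    for t in range(config.n_test_sets):
        n_ident = config.n_test_faces
        n_img = config.images_per_identity
        Z_ident = rng.standard_normal((n_ident, k))
        Z_test = np.repeat(Z_ident, n_img, axis=0)
        ids = []
        identity_map: dict[str, str] | None = {} if n_img > 1 else None
        for i in range(n_ident):
            for j in range(n_img):
                fid = f"test{t+1}_{i+1:04d}" if n_img == 1 else f"test{t+1}_{i+1:04d}_img{j+1}"
                ids.append(fid)
                if identity_map is not None:
                    identity_map[fid] = f"test{t+1}_id{i+1:04d}"
        ratings = _ratings_from_latents(Z_test, config, rng, ids)
        features = {
            spec.name: _features_from_latents(Z_test, spec, maps[spec.name], config, rng, ids)
            for spec in config.feature_space_specs
        }
        test_sets.append(SyntheticTestSet(ratings, features, identity_map, Z_test))

    true_weights = {
        spec.name: _population_weights(spec, maps[spec.name], config)
        for spec in config.feature_space_specs
    }
    return SyntheticWorld(
        config=config,
        train_ratings=train_ratings,
        train_features=train_features,
        test_sets=test_sets,
        true_weights=true_weights,
        latent_scores=Z_train,
    )


def apply_style_perturbation(
    features: FeatureTable,
    spec: FeatureSpaceSpec,
    seed: int,
    style_perturbation_sd: float = 1.0,
) -> FeatureTable:
    """Contaminate a feature space with a global image-style change.

    One random unit direction in feature space is shared by the whole
    dataset (a single style axis, as a uniform manipulation like grayscale
    conversion would induce); each face moves along it by an independent
    N(0, style_perturbation_sd) amount, attenuated by the space's
    ``style_sensitivity``. Input is not modified.
    """
    if features.space_name != spec.name:
        raise ValueError(
            f"space name mismatch: features are {features.space_name!r}, spec is {spec.name!r}"
        )
    if spec.style_sensitivity == 0 or style_perturbation_sd == 0:
        return FeatureTable(features.space_name, features.features.copy())
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(len(features.feature_names))
    direction /= np.linalg.norm(direction)
    magnitudes = style_perturbation_sd * rng.standard_normal(len(features.face_ids))
    perturbed = features.matrix + spec.style_sensitivity * np.outer(magnitudes, direction)
    return FeatureTable(
        features.space_name,
        pd.DataFrame(perturbed, index=features.features.index, columns=features.feature_names),
    )


# ---------------------------------------------------------------------------
# Landmark fixtures

# Right half of a symmetric 68-point template (iBUG 300-W ordering), in
# pixels, midline at x = 100. Jaw 0-16, brows 17-26, nose 27-35, eyes 36-47,
# mouth 48-67. Left-side points are mirror images of their right-side pairs.
_MIDLINE_X = 100.0

# (index, x, y) for the right half plus midline points; mirror partner of
# index i is _MIRROR[i].
_TEMPLATE: dict[int, tuple[float, float]] = {
    # jaw (right side 0-7, chin 8)
    0: (30.0, 110.0), 1: (32.0, 130.0), 2: (36.0, 150.0), 3: (42.0, 168.0),
    4: (50.0, 184.0), 5: (61.0, 198.0), 6: (74.0, 209.0), 7: (87.0, 216.0),
    8: (100.0, 219.0),
    # right brow 17-21
    17: (38.0, 92.0), 18: (46.0, 86.0), 19: (56.0, 84.0), 20: (66.0, 86.0),
    21: (75.0, 90.0),
    # nose bridge 27-30 (midline), base 31-35
    27: (100.0, 100.0), 28: (100.0, 112.0), 29: (100.0, 124.0), 30: (100.0, 136.0),
    31: (88.0, 146.0), 32: (94.0, 149.0), 33: (100.0, 151.0),
    # right eye 36-41
    36: (46.0, 103.0), 37: (53.0, 99.0), 38: (61.0, 99.0), 39: (68.0, 103.0),
    40: (61.0, 107.0), 41: (53.0, 107.0),
    # mouth outer: right corner 48, upper 49-50, top center 51; bottom 57-59
    48: (72.0, 178.0), 49: (81.0, 172.0), 50: (91.0, 169.0), 51: (100.0, 170.0),
    57: (100.0, 192.0), 58: (90.0, 190.0), 59: (80.0, 186.0),
    # mouth inner: right corner 60, top 61-62, bottom 66-67
    60: (77.0, 178.0), 61: (89.0, 175.0), 62: (100.0, 176.0),
    66: (100.0, 184.0), 67: (89.0, 183.0),
}

# mirror pairs (right index -> left index)
_MIRROR_PAIRS = {
    0: 16, 1: 15, 2: 14, 3: 13, 4: 12, 5: 11, 6: 10, 7: 9,
    17: 26, 18: 25, 19: 24, 20: 23, 21: 22,
    31: 35, 32: 34,
    36: 45, 37: 44, 38: 43, 39: 42, 40: 47, 41: 46,
    48: 54, 49: 53, 50: 52,
    57: 57, 58: 56, 59: 55,
    60: 64, 61: 63, 66: 66, 67: 65,
}


def template_landmarks() -> np.ndarray:
    """The symmetric 68-point template face, shape (68, 2)."""
    pts = np.full((68, 2), np.nan)
    for i, (x, y) in enumerate_template():
        pts[i] = (x, y)
    assert np.isfinite(pts).all()
    return pts


def enumerate_template():
    for i, (x, y) in _TEMPLATE.items():
        yield i, (x, y)
        if i in _MIRROR_PAIRS:
            j = _MIRROR_PAIRS[i]
            if j != i:
                yield j, (2 * _MIDLINE_X - x, y)


def _symmetrize(delta: np.ndarray) -> np.ndarray:
    """Project a 68x2 displacement field onto bilaterally symmetric fields."""
    out = delta.copy()
    for r, l in _MIRROR_PAIRS.items():
        if l == r:
            out[r, 0] = 0.0
            continue
        dx = 0.5 * (delta[r, 0] - delta[l, 0])
        dy = 0.5 * (delta[r, 1] + delta[l, 1])
        out[r] = (dx, dy)
        out[l] = (-dx, dy)
    for i in _TEMPLATE:
        if i not in _MIRROR_PAIRS:  # midline point
            out[i, 0] = 0.0
    return out


def generate_landmarks(
    n_faces: int,
    asymmetry_sd: float = 1.0,
    seed: int = 0,
    shape_sd: float = 3.0,
) -> list[dict]:
    """Seeded synthetic 68-point landmark sets (plus a skin-luminance scalar).

    Each face is the symmetric template plus a bilaterally symmetric random
    shape deformation (sd ``shape_sd`` pixels) plus left/right asymmetry
    noise (sd ``asymmetry_sd``). With ``asymmetry_sd = 0`` every face is
    exactly symmetric about its midline.

    Returns a list of dicts with keys ``face_id``, ``points`` (68 [x, y]
    pairs) and ``skin_luminance`` — the JSON landmark format.
    """
    if n_faces < 1:
        raise ValueError("n_faces must be >= 1")
    if asymmetry_sd < 0:
        raise ValueError("asymmetry_sd must be non-negative")
    rng = np.random.default_rng(seed)
    base = template_landmarks()
    faces = []
    for i in range(n_faces):
        sym = _symmetrize(shape_sd * rng.standard_normal((68, 2)))
        asym = asymmetry_sd * rng.standard_normal((68, 2))
        pts = base + sym + asym
        lum = float(np.clip(rng.normal(128.0, 25.0), 0.0, 255.0))
        faces.append(
            {
                "face_id": f"face_{i+1:04d}",
                "points": pts.tolist(),
                "skin_luminance": lum,
            }
        )
    return faces


def write_landmarks_json(faces: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(faces, fh)


def read_landmarks_json(path) -> list[dict]:
    with open(path) as fh:
        faces = json.load(fh)
    for f in faces:
        if len(f["points"]) != 68:
            raise ValueError(f"face {f.get('face_id')!r} does not have 68 points")
    return faces
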
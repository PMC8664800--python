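"""Rating and feature tables: validated faces-by-columns matrices with CSV IO.

Both containers wrap a :class:`pandas.DataFrame` indexed by ``face_id``.
A :class:`RatingTable` holds mean human ratings (faces x social attributes,
Likert units); a :class:`FeatureTable` holds one named feature space
(faces x numeric features) used as a regression design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FACE_ID_COLUMN = "face_id"


def _validate_frame(df: pd.DataFrame, what: str) -> None:
    if df.shape[1] < 1:
        raise ValueError(f"{what} must have at least one column")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{what} has duplicate face_id(s): {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{what} has a non-numeric cell at face_id={df.index[r]!r}, "
            f"column={df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{what} has a missing value at face_id={df.index[r]!r}, "
            f"column={df.columns[c]!r}"
        )


@dataclass
class RatingTable:
    """Faces x attributes matrix of mean human ratings.

    Parameters
    ----------
    ratings
        DataFrame indexed by face identifier; one column per social
        attribute, values are per-face mean Likert ratings.
    likert_min, likert_max
        Declared bounds of the rating scale. Out-of-range values are
        retained but logged as a warning.
    """

    ratings: pd.DataFrame
    likert_min: float = 1.0
    likert_max: float = 7.0

    def __post_init__(self) -> None:
        _validate_frame(self.ratings, "rating table")
        self.ratings = self.ratings.astype(float)
        self.ratings.index.name = FACE_ID_COLUMN
        vals = self.ratings.to_numpy()
        if ((vals < self.likert_min) | (vals > self.likert_max)).any():
            logger.warning(
                "rating table contains values outside the declared Likert "
                "range [%s, %s]; values retained",
                self.likert_min,
                self.likert_max,
            )

    @property
    def face_ids(self) -> list[str]:
        return list(self.ratings.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.ratings.columns)

    def column(self, attribute: str) -> np.ndarray:
        if attribute not in self.ratings.columns:
            raise KeyError(f"attribute {attribute!r} not in rating table")
        return self.ratings[attribute].to_numpy()

    def to_csv(self, path) -> None:
        self.ratings.to_csv(path, index_label=FACE_ID_COLUMN)


@dataclass
class FeatureTable:
    """Faces x features numeric matrix for one named feature space."""

    space_name: str
    features: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        _validate_frame(self.features, f"feature table {self.space_name!r}")
        self.features = self.features.astype(float)
        self.features.index.name = FACE_ID_COLUMN

    @property
    def face_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.features.to_numpy()

    def reindex(self, face_ids) -> "FeatureTable":
        missing = [f for f in face_ids if f not in self.features.index]
        if missing:
            raise KeyError(f"face_id(s) missing from feature table: {missing[:5]}")
        return FeatureTable(self.space_name, self.features.loc[list(face_ids)])

    def to_csv(self, path) -> None:
        self.features.to_csv(path, index_label=FACE_ID_COLUMN)


def concat_feature_tables(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Concatenate two feature spaces column-wise for a joint model.

    Feature names must already be disjoint; overlapping names are rejected
    so that joint-model weights remain attributable to one source space.
    """
    overlap = set(a.feature_names) & set(b.feature_names)
    if overlap:
        raise ValueError(
            f"feature name(s) {sorted(overlap)[:5]} appear in both "
            f"{a.space_name!r} and {b.space_name!r}; disambiguate before "
            "concatenation"
        )
    if list(a.face_ids) != list(b.face_ids):
        b = b.reindex(a.face_ids)
    joint = pd.concat([a.features, b.features], axis=1)
    return FeatureTable(f"{a.space_name}+{b.space_name}", joint)


def read_rating_table(path, likert_min: float = 1.0, likert_max: float = 7.0) -> RatingTable:
    """Read a rating CSV (first column ``face_id``, one column per attribute)."""
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != FACE_ID_COLUMN:
        raise ValueError(
            f"first column of {path} must be {FACE_ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    return RatingTable(df.set_index(FACE_ID_COLUMN), likert_min, likert_max)


def read_feature_table(path, space_name: str | None = None) -> FeatureTable:
    """Read a feature CSV (first column ``face_id``, one column per feature)."""
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != FACE_ID_COLUMN:
        raise ValueError(
            f"first column of {path} must be {FACE_ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    if space_name is None:
        space_name = str(path)
    return FeatureTable(space_name, df.set_index(FACE_ID_COLUMN))
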
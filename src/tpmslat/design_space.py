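"""Full-factorial design-space enumeration, size classification and encoding.

The design space is the Cartesian product of discrete levels for the seven
design parameters (surface type, per-axis unit-cell size, shell thickness,
rotation angle, cylinder height and diameter).  Squat columns are kept via a
height-to-diameter stability criterion (H/D <= max_aspect_ratio, default 2),
and each retained design is classified by implant size:

* small:  H <= 8 mm and D <= 8 mm
* large:  H > 15 mm or D > 15 mm
* medium: everything else

With the default levels this yields 3456 enumerated designs, 3024 retained,
and per-type size-class counts 72 / 504 / 432.

Features for modelling are the seven numeric parameters z-scored on the
fitted set, plus a three-column one-hot encoding of the surface type
(gyroid, diamond, split_p order).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .geometry import SURFACE_TYPES, LatticeDesign

SIZE_CLASSES = ("small", "medium", "large")

#: numeric feature columns in canonical order
NUMERIC_FEATURES = [
    "cell_size_x", "cell_size_y", "cell_size_z",
    "thickness", "rotation_deg", "height", "diameter",
]
ONEHOT_FEATURES = [f"type_{t}" for t in SURFACE_TYPES]
FEATURE_COLUMNS = NUMERIC_FEATURES + ONEHOT_FEATURES


@dataclass
class DesignSpaceConfig:
    """Levels of the full-factorial sweep plus the stability filter bound."""

    type_levels: tuple = SURFACE_TYPES
    cell_x_levels: tuple = (3.0, 4.0)
    cell_y_levels: tuple = (3.0, 4.0)
    cell_z_levels: tuple = (3.0, 4.0)
    thickness_levels: tuple = (0.2, 0.3, 0.4)
    rotation_levels: tuple = (0.0, 30.0, 60.0)
    height_levels: tuple = (8.0, 10.0, 15.0, 20.0)
    diameter_levels: tuple = (5.0, 10.0, 15.0, 20.0)
    max_aspect_ratio: float = 2.0

    def __post_init__(self) -> None:
        for name in ("type_levels", "cell_x_levels", "cell_y_levels",
                     "cell_z_levels", "thickness_levels", "rotation_levels",
                     "height_levels", "diameter_levels"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if not self.max_aspect_ratio > 0:
            raise ValueError("max_aspect_ratio must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpaceConfig":
        return cls(**{k: tuple(v) if isinstance(v, (list, tuple)) else v
                      for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "DesignSpaceConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def enumerate_full_factorial(config: DesignSpaceConfig) -> list[LatticeDesign]:
    """Cartesian product of all level lists in lexicographic order."""
    out = []
    for t, cx, cy, cz, th, rot, h, d in itertools.product(
            config.type_levels, config.cell_x_levels, config.cell_y_levels,
            config.cell_z_levels, config.thickness_levels,
            config.rotation_levels, config.height_levels,
            config.diameter_levels):
        out.append(LatticeDesign(
            surface_type=t, cell_size_x=cx, cell_size_y=cy, cell_size_z=cz,
            thickness=th, rotation_deg=rot, height=h, diameter=d))
    return out


def filter_aspect_ratio(designs, max_ratio: float = 2.0):
    """Retain squat designs with H/D <= max_ratio (order preserved)."""
    if not max_ratio > 0:
        raise ValueError("max_ratio must be > 0")
    return [d for d in designs if d.aspect_ratio <= max_ratio]


def classify_size(design: LatticeDesign) -> str:
    """Implant size class; precedence small, then large, then medium."""
    if design.height <= 8 and design.diameter <= 8:
        return "small"
    if design.height > 15 or design.diameter > 15:
        return "large"
    return "medium"


def designs_to_frame(designs, size_class: bool = True) -> pd.DataFrame:
    """One row per design in the canonical CSV schema (lengths in mm)."""
    df = pd.DataFrame([d.to_dict() for d in designs])
    if size_class:
        df["size_class"] = [classify_size(d) for d in designs]
    return df


def frame_to_designs(df: pd.DataFrame) -> list[LatticeDesign]:
    cols = ["surface_type"] + NUMERIC_FEATURES
    return [LatticeDesign(**{c: row[c] for c in cols})
            for _, row in df[cols].iterrows()]


class FeatureEncoder:
    """z-scores the numeric design parameters and one-hot encodes the type.

    Fit on a training frame; ``transform`` then maps any frame with the same
    columns to the fixed 10-column layout ``FEATURE_COLUMNS`` (7 scaled
    numerics + 3 unscaled one-hot indicators).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, df: pd.DataFrame) -> "FeatureEncoder":
        if len(df) == 0:
            raise ValueError("cannot fit an encoder on an empty dataset")
        X = df[NUMERIC_FEATURES].to_numpy(dtype=float)
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        zero = np.flatnonzero(self.std_ == 0)
        if zero.size:
            names = [NUMERIC_FEATURES[i] for i in zero]
            raise ValueError(f"zero-variance feature column(s): {names}")
        return self

    def _check_fitted(self) -> None:
        if self.mean_ is None:
            raise RuntimeError("encoder is not fitted")

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        X = df[NUMERIC_FEATURES].to_numpy(dtype=float)
        Xs = (X - self.mean_) / self.std_
        onehot = np.column_stack([
            (df["surface_type"] == t).to_numpy(dtype=float)
            for t in SURFACE_TYPES
        ])
        if not np.allclose(onehot.sum(axis=1), 1.0):
            bad = df.loc[~np.isclose(onehot.sum(axis=1), 1.0), "surface_type"]
            raise ValueError(f"unknown surface type(s): {sorted(set(bad))}")
        return np.hstack([Xs, onehot])

    def inverse_transform(self, X: np.ndarray) -> pd.DataFrame:
        self._check_fitted()
        X = np.atleast_2d(X)
        numeric = X[:, :len(NUMERIC_FEATURES)] * self.std_ + self.mean_
        df = pd.DataFrame(numeric, columns=NUMERIC_FEATURES)
        onehot = X[:, len(NUMERIC_FEATURES):]
        df["surface_type"] = [SURFACE_TYPES[i] for i in onehot.argmax(axis=1)]
        return df

    def fit_transform(self, df: pd.DataFrame) -> np.ndarray:
        return self.fit(df).transform(df)

    # -- persistence --------------------------------------------------------

    def to_json(self, path) -> None:
        self._check_fitted()
        with open(path, "w") as fh:
            json.dump({"mean": self.mean_.tolist(), "std": self.std_.tolist(),
                       "numeric_features": NUMERIC_FEATURES,
                       "onehot_features": ONEHOT_FEATURES}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FeatureEncoder":
        with open(path) as fh:
            d = json.load(fh)
        enc = cls()
        enc.mean_ = np.asarray(d["mean"], dtype=float)
        enc.std_ = np.asarray(d["std"], dtype=float)
        return enc


def encode_features(df: pd.DataFrame):
    """Fit an encoder on ``df`` and return (feature_matrix, encoder)."""
    enc = FeatureEncoder()
    return enc.fit_transform(df), enc


@dataclass
class GroupSummary:
    """Five-number summary plus Tukey-fence outlier count for one class."""

    size_class: str
    count: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    n_outliers: int
    empty: bool = False


def group_summary(df: pd.DataFrame, prop: str,
                  kde: bool = False) -> pd.DataFrame:
    """Per-size-class summary of ``prop`` (min, quartiles, max, outliers).

    Outliers use the 1.5·IQR Tukey fences.  With ``kde=True`` a column of
    Gaussian-kernel density estimates (Scott's-rule bandwidth, from scipy)
    is attached for plotting.
    """
    if prop not in df.columns:
        raise KeyError(f"property {prop!r} not in dataset")
    rows = []
    kdes = {}
    for cls in SIZE_CLASSES:
        vals = df.loc[df["size_class"] == cls, prop].to_numpy(dtype=float)
        if len(vals) == 0:
            rows.append(GroupSummary(cls, 0, *(np.nan,) * 5, 0, empty=True))
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        n_out = int(((vals < lo) | (vals > hi)).sum())
        rows.append(GroupSummary(cls, len(vals), float(vals.min()), float(q1),
                                 float(med), float(q3), float(vals.max()),
                                 n_out))
        if kde and len(vals) > 1 and vals.std() > 0:
            kdes[cls] = stats.gaussian_kde(vals)  # Scott's rule default
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("size_class")
    if kde:
        out["kde"] = pd.Series(kdes)
    return out


__all__ = [
    "SIZE_CLASSES", "NUMERIC_FEATURES", "ONEHOT_FEATURES", "FEATURE_COLUMNS",
    "DesignSpaceConfig", "enumerate_full_factorial", "filter_aspect_ratio",
    "classify_size", "designs_to_frame", "frame_to_designs", "FeatureEncoder",
    "encode_features", "GroupSummary", "group_summary",
]
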
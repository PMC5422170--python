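"""The seven-feature vector and its [0, 1] normalization.

Feature order is fixed: ``(len_AB, len_CD, len_LK, h_c, d_K, d_L, phi)``
— the silhouette diameter, its perpendicular bisector chord, the
chaff-tip width and height, the two concavity depths (pixels) and the
interior angle (degrees).  Normalization is train-set min–max with
clipping at prediction time; it is serialized with every model so the
column order cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PaddyIdError
from .geometry import SeedGeometry

__all__ = [
    "FEATURE_NAMES",
    "NormalizationRanges",
    "extract_features",
    "fit_normalization",
    "apply_normalization",
    "denormalize",
]

FEATURE_NAMES: tuple[str, ...] = (
    "len_AB",
    "len_CD",
    "len_LK",
    "h_c",
    "d_K",
    "d_L",
    "phi",
)
N_FEATURES = len(FEATURE_NAMES)


@dataclass
class NormalizationRanges:
    """Per-feature (min, max) learned from a training set.

    Degenerate features (max == min on the training set) are flagged and
    map to 0.5 at prediction time.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        return self.maxs == self.mins

    def to_dict(self) -> dict:
        return {
            "features": list(FEATURE_NAMES),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRanges":
        if list(d.get("features", FEATURE_NAMES)) != list(FEATURE_NAMES):
            raise PaddyIdError("feature-order mismatch in serialized ranges")
        return cls(mins=np.asarray(d["mins"], float), maxs=np.asarray(d["maxs"], float))


def extract_features(g: SeedGeometry) -> np.ndarray:
    """Copy the seven scalars of a completed geometry in fixed order."""
    if g.region_K is None or g.region_L is None:
        raise PaddyIdError("geometry is missing the concave regions")
    return np.array(
        [g.length_AB, g.length_CD, g.length_LK, g.h_c, g.d_K, g.d_L, g.phi],
        dtype=np.float64,
    )


def _as_matrix(vectors) -> np.ndarray:
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[-1] != N_FEATURES:
        raise PaddyIdError(f"expected {N_FEATURES} features, got {x.shape[-1]}")
    return x


def fit_normalization(train) -> NormalizationRanges:
    """Per-feature min/max over a training set of feature vectors."""
    x = _as_matrix(train)
    if len(x) == 0:
        raise PaddyIdError("cannot fit normalization on an empty set")
    return NormalizationRanges(mins=x.min(axis=0), maxs=x.max(axis=0))


def apply_normalization(v, r: NormalizationRanges) -> np.ndarray:
    """Map features into [0, 1] by the fitted ranges, clipping outliers."""
    x = _as_matrix(v)
    span = r.maxs - r.mins
    out = np.empty_like(x)
    deg = r.degenerate
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, ~deg] = (x[:, ~deg] - r.mins[~deg]) / span[~deg]
    out[:, deg] = 0.5
    out = np.clip(out, 0.0, 1.0)
    return out[0] if np.asarray(v).ndim == 1 else out


def denormalize(z, r: NormalizationRanges) -> np.ndarray:
    """Inverse of :func:`apply_normalization` for in-range values."""
    zz = _as_matrix(z)
    out = r.mins + zz * (r.maxs - r.mins)
    return out[0] if np.asarray(z).ndim == 1 else out
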
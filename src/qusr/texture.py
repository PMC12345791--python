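"""GLCM texture analysis of parametric maps and the 31-feature schema.

The grey-level co-occurrence matrix is computed over in-mask pixel pairs
only (pairs crossing the ROI boundary are ignored), symmetrised and
normalised.  Four features are derived per matrix — contrast, correlation,
homogeneity (inverse difference) and energy — and averaged over the
configured angles.  A patient-timepoint feature set holds 6 parameter
means + 24 texture values + attenuation = 31 named features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PARAMETERS = ("MBF", "SS", "SI", "SAS", "ASD", "AAC")
TEXTURES = ("CON", "COR", "HOM", "ENE")
ATTENUATION_FEATURE = "ATT"

#: Canonical ordered names of the 31 features: 6 parameter means, 24
#: parameter-texture values, and the scan-level attenuation estimate.
FEATURE_NAMES: tuple[str, ...] = (
    PARAMETERS
    + tuple(f"{p}-{t}" for p in PARAMETERS for t in TEXTURES)
    + (ATTENUATION_FEATURE,)
)

# offsets (row, col) per angle in degrees, unit distance
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    n_levels: int = 16
    quantization: str = "minmax"  # or "fixed"
    fixed_range: tuple[float, float] | None = None
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normalized: bool = True
    homogeneity_dialect: str = "inverse_difference"  # or "inverse_difference_squared"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        bad = set(self.angles) - set(_ANGLE_OFFSETS)
        if bad:
            raise ValueError(f"unsupported angles: {sorted(bad)}")
        if self.quantization not in ("minmax", "fixed"):
            raise ValueError("quantization must be 'minmax' or 'fixed'")
        if self.quantization == "fixed" and self.fixed_range is None:
            raise ValueError("fixed quantization requires fixed_range")


@dataclass(frozen=True)
class TextureFeatures:
    CON: float
    COR: float
    HOM: float
    ENE: float

    def as_dict(self) -> dict[str, float]:
        return {"CON": self.CON, "COR": self.COR, "HOM": self.HOM, "ENE": self.ENE}


def quantize_map(
    values: np.ndarray,
    mask: np.ndarray,
    config: GLCMConfig,
) -> np.ndarray:
    """Quantise map values to integer grey levels 0..n_levels-1.

    Returns an int array with -1 at excluded pixels (outside mask or
    non-finite).  Min-max quantisation uses the in-mask finite range.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    out = np.full(values.shape, -1, dtype=np.int64)
    if not mask.any():
        return out
    if config.quantization == "minmax":
        lo = values[mask].min()
        hi = values[mask].max()
    else:
        lo, hi = config.fixed_range  # type: ignore[misc]
    if hi <= lo:
        out[mask] = 0  # constant map -> single level
        return out
    scaled = (values - lo) / (hi - lo) * config.n_levels
    out[mask] = np.clip(scaled[mask].astype(np.int64), 0, config.n_levels - 1)
    return out


def compute_glcm(
    levels: np.ndarray,
    config: GLCMConfig,
    angle: int = 0,
) -> np.ndarray:
    """Co-occurrence matrix for one angle over valid (level >= 0) pixel pairs.

    ``levels`` is an integer map as produced by :func:`quantize_map`.
    Symmetrised and normalised per the config; raises if no valid pair
    exists at the configured offset.
    """
    levels = np.asarray(levels)
    if levels.ndim != 2:
        raise ValueError("levels map must be 2-D")
    dr, dc = _ANGLE_OFFSETS[angle]
    dr *= config.distance
    dc *= config.distance
    nr, nc = levels.shape
    r0s, r0e = max(0, -dr), min(nr, nr - dr)
    c0s, c0e = max(0, -dc), min(nc, nc - dc)
    a = levels[r0s:r0e, c0s:c0e]
    b = levels[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        raise ValueError("no valid in-mask pixel pairs at the configured offset")
    i = a[valid].ravel()
    j = b[valid].ravel()
    n = config.n_levels
    p = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    if config.symmetric:
        p = p + p.T
    if config.normalized:
        p /= p.sum()
    return p


def glcm_brute_force(
    levels: np.ndarray, config: GLCMConfig, angle: int = 0
) -> np.ndarray:
    """Reference implementation: explicit python loop over all pixel pairs.

    Kept for oracle testing of :func:`compute_glcm`; do not use on large maps.
    """
    levels = np.asarray(levels)
    dr, dc = _ANGLE_OFFSETS[angle]
    dr *= config.distance
    dc *= config.distance
    n = config.n_levels
    p = np.zeros((n, n))
    nr, nc = levels.shape
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and levels[r, c] >= 0 and levels[r2, c2] >= 0:
                p[levels[r, c], levels[r2, c2]] += 1
    if p.sum() == 0:
        raise ValueError("no valid in-mask pixel pairs at the configured offset")
    if config.symmetric:
        p = p + p.T
    if config.normalized:
        p /= p.sum()
    return p


def texture_features(glcm: np.ndarray, config: GLCMConfig | None = None) -> TextureFeatures:
    """Contrast, correlation, homogeneity and energy of a normalised GLCM."""
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalised (sum to 1)")
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j
    con = float(np.sum(p * diff**2))
    dialect = (config.homogeneity_dialect if config else "inverse_difference")
    if dialect == "inverse_difference":
        hom = float(np.sum(p / (1.0 + np.abs(diff))))
    else:
        hom = float(np.sum(p / (1.0 + diff**2)))
    ene = float(np.sum(p**2))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    if var_i <= 0 or var_j <= 0:
        cor = 1.0  # degenerate single-level map: perfectly correlated by convention
    else:
        cor = float(np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))
    return TextureFeatures(CON=con, COR=cor, HOM=hom, ENE=ene)


def map_texture_features(
    values: np.ndarray, mask: np.ndarray, config: GLCMConfig | None = None
) -> TextureFeatures:
    """Quantise a masked map and return angle-averaged texture features."""
    config = config or GLCMConfig()
    levels = quantize_map(values, mask, config)
    feats = []
    for ang in config.angles:
        feats.append(texture_features(compute_glcm(levels, config, ang), config))
    arr = np.array([[f.CON, f.COR, f.HOM, f.ENE] for f in feats])
    m = arr.mean(axis=0)
    return TextureFeatures(*m)


@dataclass(frozen=True)
class QUSFeatureSet:
    """The 31 named features of one patient-timepoint."""

    patient_id: str
    week: int
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(
                f"feature schema violation: missing={sorted(missing)} extra={sorted(extra)}"
            )
        object.__setattr__(self, "values", dict(self.values))

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES}, name=self.patient_id)


@dataclass(frozen=True)
class DeltaFeatureSet:
    """Week-1 minus week-0 feature differences for one patient."""

    patient_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(
                f"feature schema violation: missing={sorted(missing)} extra={sorted(extra)}"
            )
        object.__setattr__(self, "values", dict(self.values))

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES}, name=self.patient_id)


def assemble_features(
    patient_id: str,
    week: int,
    maps: Sequence,  # per-frame lists of qus_params.ParametricMap
    attenuation: float,
    glcm_config: GLCMConfig | None = None,
) -> QUSFeatureSet:
    """Build the 31-feature set from per-frame parametric maps + attenuation.

    ``maps`` is a flat sequence of ParametricMap objects covering all frames;
    exactly the six parameters must each appear the same number of times
    (once per frame).  Parameter means pool every valid window across frames;
    texture features are computed per frame and averaged across frames.
    """
    glcm_config = glcm_config or GLCMConfig()
    by_param: dict[str, list] = {p: [] for p in PARAMETERS}
    for m in maps:
        if m.parameter_id not in by_param:
            raise ValueError(f"unknown parameter map {m.parameter_id!r}")
        by_param[m.parameter_id].append(m)
    counts = {p: len(v) for p, v in by_param.items()}
    missing = [p for p, c in counts.items() if c == 0]
    if missing:
        raise ValueError(f"missing parameter maps: {missing}")
    if len(set(counts.values())) != 1:
        raise ValueError(f"unbalanced parameter maps per frame: {counts}")

    values: dict[str, float] = {}
    for p, plist in by_param.items():
        pooled = np.concatenate([m.valid_values() for m in plist])
        values[p] = float(np.mean(pooled)) if pooled.size else float("nan")
        tex = [map_texture_features(m.values, m.finite_mask(), glcm_config) for m in plist]
        arr = np.array([[t.CON, t.COR, t.HOM, t.ENE] for t in tex])
        for k, t in enumerate(TEXTURES):
            values[f"{p}-{t}"] = float(arr[:, k].mean())
    values[ATTENUATION_FEATURE] = float(attenuation)
    return QUSFeatureSet(patient_id=patient_id, week=week, values=values)


def delta_features(week0: QUSFeatureSet, week1: QUSFeatureSet) -> DeltaFeatureSet:
    """Element-wise week1 - week0 differences."""
    if week0.patient_id != week1.patient_id:
        raise ValueError(
            f"patient mismatch: {week0.patient_id!r} vs {week1.patient_id!r}"
        )
    d = {k: week1.values[k] - week0.values[k] for k in FEATURE_NAMES}
    return DeltaFeatureSet(patient_id=week0.patient_id, values=d)


def feature_table(feature_sets: Sequence[QUSFeatureSet]) -> pd.DataFrame:
    """Tabulate feature sets: one row per patient-week, 31 named columns."""
    rows = []
    for fs in feature_sets:
        row = {"patient_id": fs.patient_id, "week": fs.week}
        row.update({k: fs.values[k] for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def delta_table(deltas: Sequence[DeltaFeatureSet]) -> pd.DataFrame:
    rows = []
    for d in deltas:
        row = {"patient_id": d.patient_id}
        row.update({k: d.values[k] for k in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
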
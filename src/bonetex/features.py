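"""The 45-feature histogram / GLCM texture grid.

Five intensity features are computed from the ROI histogram (mean,
standard deviation, skewness, kurtosis, entropy) and forty texture
features from gray-level co-occurrence matrices (GLCMs) over the full
grid of 2 offset directions (horizontal, vertical) × 4 quantization
levels (16, 32, 64, 128) × 5 statistics (contrast, correlation, energy,
homogeneity, variance).

Conventions, stated because they matter for reproducibility:

* moments are population moments; kurtosis is the raw fourth
  standardized moment (3 for a Gaussian), not excess;
* histogram entropy uses 256 equal bins spanning the ROI min–max and
  log base 2, with 0·log 0 = 0;
* quantization is min–max within the ROI (an optional fixed-HU-window
  mode is available for cross-subject comparability);
* GLCMs use offset distance 1, are symmetric and normalized by default;
* feature order is frozen and versioned (:data:`FEATURE_NAMES`,
  :data:`~bonetex.core.FEATURE_ORDER_VERSION`) so weight vectors are
  portable between runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ContractError, DegenerateGLCMError, InvalidParameterError
from .roi import TrabecularROI

__all__ = [
    "GLCMConfig",
    "GLCM",
    "FeatureVector",
    "FEATURE_NAMES",
    "histogram_features",
    "quantize",
    "compute_glcm",
    "glcm_statistics",
    "glcm_autocorrelation",
    "extract_features",
]

ALLOWED_LEVELS = (16, 32, 64, 128)
DIRECTIONS = ("H", "V")
GLCM_STAT_NAMES = ("Contrast", "Correlation", "Energy", "Homogeneity", "Variance")
HISTOGRAM_NAMES = ("Mean", "SD", "Skewness", "Kurtosis", "Entropy")

#: Frozen order of the 45 features: 5 histogram statistics, then
#: direction-major (H, V) × level (16, 32, 64, 128) × statistic
#: (contrast, correlation, energy, homogeneity, variance).
FEATURE_NAMES: tuple[str, ...] = HISTOGRAM_NAMES + tuple(
    f"{stat}_{d}_{lv}"
    for d in DIRECTIONS
    for lv in ALLOWED_LEVELS
    for stat in GLCM_STAT_NAMES
)
assert len(FEATURE_NAMES) == 45


@dataclass(frozen=True)
class GLCMConfig:
    """Offset and normalization choices for one co-occurrence matrix."""

    direction: str = "H"  # "H" (row, col+d) or "V" (row+d, col)
    levels: int = 16
    offset_distance: int = 1
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise InvalidParameterError("direction must be 'H' or 'V'")
        if self.levels not in ALLOWED_LEVELS:
            raise InvalidParameterError(f"levels must be one of {ALLOWED_LEVELS}")
        if self.offset_distance < 1:
            raise InvalidParameterError("offset_distance must be >= 1")


@dataclass
class GLCM:
    """Gray-level co-occurrence matrix p(i, j) with its provenance."""

    matrix: np.ndarray
    config: GLCMConfig
    pair_count: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.config.levels, self.config.levels):
            raise InvalidParameterError("GLCM shape does not match config.levels")
        if (self.matrix < 0).any():
            raise InvalidParameterError("GLCM entries must be >= 0")


def histogram_features(roi: TrabecularROI) -> tuple[float, float, float, float, float]:
    """Intensity statistics of the ROI: (mean, sd, skewness, kurtosis, entropy).

    A constant ROI is legal and yields sd = skewness = kurtosis = entropy = 0.
    """
    x = np.asarray(roi.pixels, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("histogram features need >= 2 pixels")
    mean = float(x.mean())
    centered = x - mean
    var = float(np.mean(centered**2))
    sd = float(np.sqrt(var))
    if sd == 0.0:
        return mean, 0.0, 0.0, 0.0, 0.0
    skew = float(np.mean(centered**3) / sd**3)
    kurt = float(np.mean(centered**4) / sd**4)

    counts, _ = np.histogram(x, bins=256, range=(float(x.min()), float(x.max())))
    p = counts[counts > 0] / x.size
    entropy = float(-np.sum(p * np.log2(p)))
    return mean, sd, skew, kurt, entropy


def quantize(roi: TrabecularROI, levels: int) -> np.ndarray:
    """Min–max quantize the slice under the ROI to integer bins 0..levels-1.

    ``bin = floor((v - min) / (max - min) · levels)`` clamped to
    ``levels - 1``; a constant ROI maps everything to bin 0.  Returns a
    full-size integer grid (values outside the mask are computed with the
    same map but carry no meaning there).
    """
    if levels not in ALLOWED_LEVELS:
        raise InvalidParameterError(f"levels must be one of {ALLOWED_LEVELS}")
    vals = roi.pixels
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return np.zeros_like(roi.image, dtype=np.intp)
    q = np.floor((roi.image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def quantize_fixed(
    roi: TrabecularROI, levels: int, window: tuple[float, float] = (0.0, 400.0)
) -> np.ndarray:
    """Quantize against a fixed HU window instead of the ROI min–max.

    Bins are comparable across subjects; out-of-window values clamp to the
    end bins.
    """
    if levels not in ALLOWED_LEVELS:
        raise InvalidParameterError(f"levels must be one of {ALLOWED_LEVELS}")
    lo, hi = window
    if hi <= lo:
        raise InvalidParameterError("window must satisfy low < high")
    q = np.floor((roi.image - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(quantized: np.ndarray, mask: np.ndarray, config: GLCMConfig) -> GLCM:
    """Count co-occurring pixel pairs under the mask at the configured offset.

    Horizontal pairs are ((r, c), (r, c+d)); vertical pairs ((r, c),
    (r+d, c)).  Both pixels must lie inside the mask.  With
    ``symmetric`` the reversed pair is counted as well; with
    ``normalize`` counts are divided by their total.
    """
    q = np.asarray(quantized)
    mask = np.asarray(mask, dtype=bool)
    if q.shape != mask.shape:
        raise InvalidParameterError("quantized grid and mask shapes differ")
    if q.min() < 0 or q.max() >= config.levels:
        raise ContractError("grid is not quantized to config.levels")

    d = config.offset_distance
    if config.direction == "H":
        a, b = q[:, :-d], q[:, d:]
        valid = mask[:, :-d] & mask[:, d:]
    else:
        a, b = q[:-d, :], q[d:, :]
        valid = mask[:-d, :] & mask[d:, :]

    i, j = a[valid], b[valid]
    if i.size == 0:
        raise DegenerateGLCMError(
            f"no valid {config.direction} pair at distance {d}"
        )

    counts = np.zeros((config.levels, config.levels), dtype=float)
    np.add.at(counts, (i, j), 1.0)
    if config.symmetric:
        np.add.at(counts, (j, i), 1.0)

    pair_count = int(counts.sum())
    matrix = counts / pair_count if config.normalize else counts
    return GLCM(matrix=matrix, config=config, pair_count=pair_count)


def _marginal_moments(p: np.ndarray):
    levels = p.shape[0]
    idx = np.arange(levels, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(idx @ pi)
    mu_j = float(idx @ pj)
    sig_i = float(np.sqrt(((idx - mu_i) ** 2) @ pi))
    sig_j = float(np.sqrt(((idx - mu_j) ** 2) @ pj))
    return idx, mu_i, mu_j, sig_i, sig_j


def glcm_statistics(glcm: GLCM) -> tuple[float, float, float, float, float]:
    """(contrast, correlation, energy, homogeneity, variance) of a normalized GLCM.

    * contrast    = Σ p(i,j) (i−j)²
    * correlation = Σ p(i,j) (i−μᵢ)(j−μⱼ) / (σᵢ σⱼ), 0 when σᵢσⱼ = 0
    * energy      = Σ p(i,j)²
    * homogeneity = Σ p(i,j) / (1 + |i−j|)
    * variance    = Σ p(i,j) (i−μᵢ)²

    with μ/σ the row/column marginal means and SDs.
    """
    p = glcm.matrix
    if abs(float(p.sum()) - 1.0) > 1e-9:
        raise ContractError("glcm_statistics requires a normalized GLCM")

    idx, mu_i, mu_j, sig_i, sig_j = _marginal_moments(p)
    ii = idx[:, None]
    jj = idx[None, :]

    contrast = float(np.sum(p * (ii - jj) ** 2))
    denom = sig_i * sig_j
    correlation = (
        0.0 if denom == 0.0 else float(np.sum(p * (ii - mu_i) * (jj - mu_j)) / denom)
    )
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    variance = float(np.sum(p * (ii - mu_i) ** 2))
    return contrast, correlation, energy, homogeneity, variance


def glcm_autocorrelation(glcm: GLCM) -> float:
    """Autocorrelation Σ i·j·p(i,j): an optional extra statistic outside
    the canonical 45-feature grid."""
    p = glcm.matrix
    if abs(float(p.sum()) - 1.0) > 1e-9:
        raise ContractError("glcm_autocorrelation requires a normalized GLCM")
    idx = np.arange(p.shape[0], dtype=float)
    return float(np.sum(p * idx[:, None] * idx[None, :]))


@dataclass
class FeatureVector:
    """The 45 named features of one ROI, in the frozen grid order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (45,):
            raise InvalidParameterError("FeatureVector must hold exactly 45 values")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("FeatureVector contains non-finite values")

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def __len__(self) -> int:
        return 45

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


def extract_features(
    roi: TrabecularROI,
    offset_distance: int = 1,
    symmetric: bool = True,
    quantization: str = "minmax",
    hu_window: tuple[float, float] = (0.0, 400.0),
) -> FeatureVector:
    """Compute the full 45-feature vector of one ROI.

    ``quantization`` is ``"minmax"`` (per-ROI, default) or ``"fixed"``
    (shared HU window, for cross-subject comparability).
    """
    if quantization not in ("minmax", "fixed"):
        raise InvalidParameterError("quantization must be 'minmax' or 'fixed'")
    out = list(histogram_features(roi))

    quantized = {}
    for lv in ALLOWED_LEVELS:
        if quantization == "minmax":
            quantized[lv] = quantize(roi, lv)
        else:
            quantized[lv] = quantize_fixed(roi, lv, hu_window)

    for d in DIRECTIONS:
        for lv in ALLOWED_LEVELS:
            cfg = GLCMConfig(
                direction=d,
                levels=lv,
                offset_distance=offset_distance,
                symmetric=symmetric,
                normalize=True,
            )
            glcm = compute_glcm(quantized[lv], roi.mask, cfg)
            out.extend(glcm_statistics(glcm))

    return FeatureVector(values=np.array(out))


def features_to_frame(ids, vectors) -> "pd.DataFrame":
    """Assemble per-subject feature vectors into a DataFrame (id + 45 columns)."""
    import pandas as pd

    data = {"id": list(ids)}
    arr = np.vstack([fv.values for fv in vectors])
    for k, name in enumerate(FEATURE_NAMES):
        data[name] = arr[:, k]
    return pd.DataFrame(data)
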
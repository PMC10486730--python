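"""Shared containers, error types and slice file I/O.

The package works on single 2D axial CT cuts in Hounsfield units (HU).
A :class:`CTSlice` is the raw input to every downstream stage; slices are
stored on disk as a raw ``.npy`` grid plus a small JSON sidecar carrying
pixel spacing and the HU offset/scale used when an integer encoding was
chosen.  A 16-bit PNG export and a minimal DICOM reading adapter are
provided for interoperability; neither is required by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FEATURE_ORDER_VERSION = "bonetex-45-v1"
"""Version tag of the frozen 45-feature order; stamped into every model file."""


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class BonetexError(Exception):
    """Base class for all package-specific failures."""


class InvalidParameterError(BonetexError, ValueError):
    """A configuration or argument violates its documented invariant."""


class EmptyROIError(BonetexError):
    """No pixel of the slice falls inside the HU threshold window."""


class TooSmallROIError(BonetexError):
    """The thresholded component is too small to inscribe a circle."""


class DegenerateGLCMError(BonetexError):
    """No valid co-occurring pixel pair exists for the requested offset."""


class ContractError(BonetexError):
    """An operation received input violating its stated contract."""


class UnderdeterminedFitError(BonetexError):
    """Fewer subjects than design columns: the normal-equation fit is underdetermined."""


class TrainingDivergedError(BonetexError):
    """ANN training produced a non-finite loss."""


class InsufficientSampleError(BonetexError):
    """Residual degrees of freedom are non-positive; no inference possible."""


class UndefinedCorrelationError(BonetexError):
    """Pearson correlation is undefined (zero variance in one argument)."""


class CohortSchemaError(BonetexError):
    """Cohort table is missing required columns or has malformed values."""


# ---------------------------------------------------------------------------
# CTSlice container
# ---------------------------------------------------------------------------

@dataclass
class CTSlice:
    """A single 2D axial CT cut.

    Parameters
    ----------
    hu:
        2D float array of attenuation values in Hounsfield units
        (water = 0, air = -1000).
    pixel_spacing:
        (row, column) pixel size in millimetres.
    meta:
        Free-form metadata (subject id, acquisition notes).
    """

    hu: np.ndarray
    pixel_spacing: tuple[float, float] = (0.7, 0.7)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 2:
            raise InvalidParameterError("CTSlice.hu must be a 2D array")
        if not np.all(np.isfinite(self.hu)):
            raise InvalidParameterError("CTSlice.hu contains non-finite values")
        if any(s <= 0 for s in self.pixel_spacing):
            raise InvalidParameterError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hu.shape


# ---------------------------------------------------------------------------
# Slice I/O: .npy grid + JSON sidecar; optional 16-bit PNG; DICOM adapter
# ---------------------------------------------------------------------------

def save_slice(ct: CTSlice, stem: str | Path) -> Path:
    """Write ``<stem>.npy`` (float64 HU grid) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), ct.hu)
    sidecar = {
        "pixel_spacing_mm": list(ct.pixel_spacing),
        "hu_offset": 0.0,
        "hu_scale": 1.0,
        "meta": ct.meta,
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return stem.with_suffix(".npy")


def load_slice(stem: str | Path) -> CTSlice:
    """Read a slice written by :func:`save_slice` (or a PNG export)."""
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    npy = stem.with_suffix(".npy")
    if npy.exists():
        raw = np.load(npy).astype(float)
    else:
        from PIL import Image  # pillow; only needed for the PNG route

        raw = np.asarray(Image.open(stem.with_suffix(".png")), dtype=float)
    hu = raw * sidecar.get("hu_scale", 1.0) + sidecar.get("hu_offset", 0.0)
    return CTSlice(
        hu=hu,
        pixel_spacing=tuple(sidecar.get("pixel_spacing_mm", (0.7, 0.7))),
        meta=sidecar.get("meta", {}),
    )


def export_png(ct: CTSlice, stem: str | Path) -> Path:
    """Export a slice as 16-bit grayscale PNG with an HU offset/scale sidecar."""
    from PIL import Image

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    lo, hi = float(ct.hu.min()), float(ct.hu.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    raw = np.round((ct.hu - lo) / scale).astype(np.uint16)
    Image.fromarray(raw, mode="I;16").save(stem.with_suffix(".png"))
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "pixel_spacing_mm": list(ct.pixel_spacing),
                "hu_offset": lo,
                "hu_scale": scale,
                "meta": ct.meta,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return stem.with_suffix(".png")


def read_dicom_slice(path: str | Path) -> CTSlice:
    """Adapter reading one axial DICOM file into a :class:`CTSlice`.

    Applies RescaleSlope/RescaleIntercept to obtain HU. Requires pydicom
    (installed via the ``dicom`` extra).
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    hu = ds.pixel_array.astype(float) * float(
        getattr(ds, "RescaleSlope", 1.0)
    ) + float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = tuple(float(v) for v in getattr(ds, "PixelSpacing", (0.7, 0.7)))
    return CTSlice(hu=hu, pixel_spacing=spacing, meta={"source": str(path)})
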
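"""Trabecular region-of-interest isolation by HU thresholding.

A single axial cut is reduced to a circular trabecular ROI in three
steps: keep pixels inside a Hounsfield-unit window that captures
trabecular bone while excluding the dense cortical shell, take the
largest connected component of those pixels, and inscribe the largest
circle in that component (found at the maximum of the Euclidean
distance transform), optionally shrunk by a safety margin to stay clear
of the cortical boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    CTSlice,
    EmptyROIError,
    InvalidParameterError,
    TooSmallROIError,
)

__all__ = ["ThresholdConfig", "TrabecularROI", "extract_roi", "select_slice"]


@dataclass(frozen=True)
class ThresholdConfig:
    """HU window and circle-fitting choices for ROI extraction.

    Defaults keep 0–400 HU: above fat/soft tissue, below cortical bone.
    ``roi_shape`` selects either the largest circle inscribed in the
    thresholded component (default) or a fixed-radius circle at the
    component centroid; either is shrunk by ``circle_margin_frac``.
    """

    hu_low: float = 0.0
    hu_high: float = 400.0
    roi_shape: str = "largest-component-inscribed-circle"
    circle_margin_frac: float = 0.1
    fixed_radius: float = 10.0  # used only when roi_shape == "fixed-circle"

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise InvalidParameterError("hu_low must be < hu_high")
        if not 0.0 <= self.circle_margin_frac < 1.0:
            raise InvalidParameterError("circle_margin_frac must be in [0, 1)")
        if self.roi_shape not in (
            "largest-component-inscribed-circle",
            "fixed-circle",
        ):
            raise InvalidParameterError(f"unknown roi_shape {self.roi_shape!r}")


@dataclass
class TrabecularROI:
    """Circular trabecular region of one slice.

    ``mask`` is aligned to ``image`` (the full HU grid, kept so that
    spatially-aware features can be computed); ``pixels`` are the HU
    values under the mask in row-major order. ``center`` is (row, col)
    in 0-based pixel coordinates and ``radius`` is in pixels.
    """

    mask: np.ndarray
    image: np.ndarray
    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.image.shape:
            raise InvalidParameterError("mask and image shapes differ")
        if not self.mask.any():
            raise InvalidParameterError("ROI mask is empty")

    @property
    def pixels(self) -> np.ndarray:
        return self.image[self.mask]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


_CONN8 = ndimage.generate_binary_structure(2, 2)


def extract_roi(ct: CTSlice, config: ThresholdConfig | None = None) -> TrabecularROI:
    """Isolate the circular trabecular ROI of one slice.

    Raises :class:`EmptyROIError` when no pixel lies in the HU window and
    :class:`TooSmallROIError` when the largest component cannot hold a
    circle of radius >= 1 pixel after the margin shrink.
    """
    config = config if config is not None else ThresholdConfig()
    hu = ct.hu
    in_window = (hu >= config.hu_low) & (hu <= config.hu_high)
    if not in_window.any():
        raise EmptyROIError(
            f"no pixel inside [{config.hu_low}, {config.hu_high}] HU"
        )

    labels, n_comp = ndimage.label(in_window, structure=_CONN8)
    sizes = ndimage.sum_labels(in_window, labels, index=np.arange(1, n_comp + 1))
    comp = labels == (int(np.argmax(sizes)) + 1)
    if comp.sum() < 2:
        raise TooSmallROIError("largest in-window component has < 2 pixels")

    if config.roi_shape == "largest-component-inscribed-circle":
        dist = ndimage.distance_transform_edt(comp)
        center_idx = np.unravel_index(int(np.argmax(dist)), dist.shape)
        radius = float(dist[center_idx]) * (1.0 - config.circle_margin_frac)
        center = (float(center_idx[0]), float(center_idx[1]))
    else:  # fixed-circle at component centroid
        cy, cx = ndimage.center_of_mass(comp)
        center = (float(cy), float(cx))
        radius = config.fixed_radius * (1.0 - config.circle_margin_frac)

    if radius < 1.0:
        raise TooSmallROIError(
            f"inscribed radius {radius:.2f} px is below 1 px after margin"
        )

    yy, xx = np.mgrid[0 : hu.shape[0], 0 : hu.shape[1]]
    mask = np.hypot(yy - center[0], xx - center[1]) <= radius
    return TrabecularROI(mask=mask, image=hu, center=center, radius=radius)


def select_slice(slices: list[CTSlice], config: ThresholdConfig | None = None) -> int:
    """Pick the stack index maximizing the in-window pixel count.

    Thin helper emulating the choice of the axial cut with maximal
    trabecular area from a stack.
    """
    config = config if config is not None else ThresholdConfig()
    counts = [
        int(((s.hu >= config.hu_low) & (s.hu <= config.hu_high)).sum())
        for s in slices
    ]
    if not counts:
        raise InvalidParameterError("empty slice stack")
    return int(np.argmax(counts))


def export_mask_png(roi: TrabecularROI, path) -> None:
    """Write the ROI mask as an 8-bit PNG for visual QC."""
    from PIL import Image

    Image.fromarray((roi.mask * 255).astype(np.uint8)).save(str(path))
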
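"""Cell-edge detection and per-cell binding quantification.

Segmentation is a standard threshold+morphology pipeline: Gaussian smoothing,
automatic (Otsu) threshold — on intensity for the fluorescence channel, on
local gradient magnitude for bright-field — morphological closing, hole
filling, and retention of the largest connected component.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "CellMask",
    "BindingMeasurement",
    "detect_cell_edge",
    "mean_cell_intensity",
    "normalize_binding",
    "corner_background_mask",
]


@dataclass
class CellMask:
    mask: np.ndarray
    source_channel: str
    area: int
    method_params: dict[str, Any] = field(default_factory=dict)


@dataclass
class BindingMeasurement:
    """Background-subtracted per-cell mean intensity for one condition."""

    mean_intensity: float
    condition_label: str
    normalized_value: float | None = None


def detect_cell_edge(image: np.ndarray, channel: str = "fluorescence", *,
                     smooth_sigma: float = 2.0, closing_radius: int = 5,
                     min_area: int = 500) -> CellMask:
    """Segment the single dominant cell in a one-channel image.

    ``channel`` selects the thresholded quantity: smoothed intensity for
    'fluorescence', smoothed gradient magnitude for 'brightfield'.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.ptp(image) == 0:
        raise ValueError("constant image; nothing to segment")
    if channel not in ("fluorescence", "brightfield"):
        raise ValueError(f"unknown channel {channel!r}")

    smoothed = ndimage.gaussian_filter(image, smooth_sigma)
    if channel == "brightfield":
        feature = filters.sobel(smoothed)
    else:
        feature = smoothed
    binary = feature > filters.threshold_otsu(feature)
    binary = morphology.closing(binary, morphology.disk(closing_radius))
    binary = ndimage.binary_fill_holes(binary)

    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError("no component found above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    if mask.sum() < min_area:
        raise ValueError(
            f"largest component has {int(mask.sum())} px < min_area {min_area}")
    return CellMask(
        mask=mask, source_channel=channel, area=int(mask.sum()),
        method_params={"smooth_sigma": smooth_sigma,
                       "closing_radius": closing_radius, "min_area": min_area},
    )


def corner_background_mask(shape: tuple[int, int], size: int = 32,
                           corner: str = "tl") -> np.ndarray:
    """Square background region in an image corner."""
    mask = np.zeros(shape, dtype=bool)
    ys = slice(0, size) if corner[0] == "t" else slice(shape[0] - size, shape[0])
    xs = slice(0, size) if corner[1] == "l" else slice(shape[1] - size, shape[1])
    mask[ys, xs] = True
    return mask


def mean_cell_intensity(image: np.ndarray, mask: CellMask | np.ndarray,
                        background_region: np.ndarray) -> float:
    """Mean over the cell mask minus mean over the background region;
    negative results are reported as-is."""
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    bg = np.asarray(background_region, dtype=bool)
    if m.shape != image.shape or bg.shape != image.shape:
        raise ValueError("mask/background shape does not match image")
    if not m.any():
        raise ValueError("empty cell mask")
    if not bg.any():
        raise ValueError("empty background region")
    if (m & bg).any():
        raise ValueError("cell mask and background region overlap")
    image = np.asarray(image, dtype=float)
    return float(image[m].mean() - image[bg].mean())


def normalize_binding(measurements: Sequence[BindingMeasurement],
                      baseline_label: str = "untreated") -> list[BindingMeasurement]:
    """Ratio each measurement to the mean of the baseline condition."""
    baseline = [m.mean_intensity for m in measurements
                if m.condition_label == baseline_label]
    if not baseline:
        raise ValueError(f"no measurement with baseline label {baseline_label!r}")
    ref = float(np.mean(baseline))
    if ref <= 0:
        raise ValueError(f"baseline mean is non-positive ({ref:.4g})")
    return [dataclasses.replace(m, normalized_value=m.mean_intensity / ref)
            for m in measurements]
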
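"""Azimuthally averaged, photobleach-corrected radial recovery profiles.

Frames at labelled timepoints (before, after, half, final) are corrected by
the per-frame scalar reference factor (the same factor the curve-level
correction uses), then averaged in annular bins by pixel-centre distance
from the bleach-disc centre.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quant import (RecoveryCurve, RoiSet, correct_photobleach, extract_traces,
                    final_recovery, half_recovery_time, normalize_prebleach,
                    renormalize_postbleach)
from .synthetic import ImageSeries

__all__ = ["RadialProfile", "radial_profiles", "average_profiles",
           "TIMEPOINT_LABELS"]

TIMEPOINT_LABELS = ("before", "after", "half", "final")


@dataclass
class RadialProfile:
    """Binned radial intensity profile at one labelled timepoint."""

    bin_centers: np.ndarray          # um from disc centre
    mean_intensity: np.ndarray       # photobleach-corrected, per bin
    sd_intensity: np.ndarray         # across replicates (0 for single frame)
    counts: np.ndarray               # pixels (or replicates) per bin
    timepoint_label: str
    max_radius: float
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.bin_centers) == len(self.mean_intensity)
                == len(self.sd_intensity) == len(self.counts)):
            raise ValueError("profile arrays have mismatched lengths")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")


def _resolve_frames(curve: RecoveryCurve, timepoints: Sequence[str],
                    n_frames: int, frame_interval: float,
                    tau_half: float | None) -> dict[str, int]:
    b = curve.bleach_index
    out: dict[str, int] = {}
    for label in timepoints:
        if label == "before":
            out[label] = b - 1
        elif label == "after":
            out[label] = b
        elif label == "final":
            out[label] = n_frames - 1
        elif label == "half":
            if tau_half is None or not np.isfinite(tau_half):
                raise ValueError(
                    "timepoint 'half' requested but no half-recovery time "
                    "is available (non-recovering curve?)")
            out[label] = min(n_frames - 1, b + int(round(tau_half / frame_interval)))
        else:
            raise ValueError(
                f"unknown timepoint {label!r}; valid: {', '.join(TIMEPOINT_LABELS)}")
    return out


def radial_profiles(series: ImageSeries, rois: RoiSet,
                    timepoints: Sequence[str] = TIMEPOINT_LABELS,
                    max_radius: float = 7.0, bin_width: float = 0.25,
                    center: tuple[float, float] | None = None,
                    tau_half: float | None = None) -> list[RadialProfile]:
    """Corrected radial profiles around the bleach disc at the requested
    timepoints.

    ``center`` defaults to the bleach-disc centre.  ``tau_half`` (needed only
    for the 'half' label) is measured from the series itself when not given.
    """
    if bin_width <= 0 or max_radius <= bin_width:
        raise ValueError("need 0 < bin_width < max_radius")
    cx, cy = center if center is not None else rois.bleach_disc.center
    ny, nx = series.shape
    ps = series.pixel_size
    if (cx - max_radius < 0 or cy - max_radius < 0
            or cx + max_radius > (nx - 1) * ps or cy + max_radius > (ny - 1) * ps):
        raise ValueError(f"disc of radius {max_radius} um around ({cx:.2f}, "
                         f"{cy:.2f}) um extends outside the image")

    curve = extract_traces(series, rois)
    curve = correct_photobleach(curve)
    if tau_half is None and "half" in timepoints:
        c2 = renormalize_postbleach(normalize_prebleach(curve))
        i_f = final_recovery(c2)
        _, _, tau_half = half_recovery_time(c2, i_f)

    frames = _resolve_frames(curve, timepoints, series.n_frames,
                             series.frame_interval, tau_half)

    # eq-2.1-style per-frame scalar factor from the ROI traces
    ref = curve.I_r - curve.I_b
    pre_ref = ref[: curve.n_prebleach].mean()
    factors = pre_ref / ref

    y = np.arange(ny) * ps
    x = np.arange(nx) * ps
    r = np.hypot(y[:, None] - cy, x[None, :] - cx)
    edges = np.arange(0.0, max_radius + bin_width / 2, bin_width)
    if edges[-1] < max_radius:
        edges = np.append(edges, max_radius)
    idx = np.digitize(r.ravel(), edges) - 1
    n_bins = len(edges) - 1
    inside = (idx >= 0) & (idx < n_bins)

    counts = np.bincount(idx[inside], minlength=n_bins)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(f"annular bin {int(empty[0])} contains no pixel; "
                         "widen bin_width")

    profiles = []
    for label, k in frames.items():
        corrected = (series.frames[k].astype(float) - curve.I_b[k]) * factors[k]
        sums = np.bincount(idx[inside], weights=corrected.ravel()[inside],
                           minlength=n_bins)
        profiles.append(RadialProfile(
            bin_centers=0.5 * (edges[:-1] + edges[1:]),
            mean_intensity=sums / counts,
            sd_intensity=np.zeros(n_bins),
            counts=counts.copy(),
            timepoint_label=label,
            max_radius=max_radius,
            frame_index=k,
        ))
    return profiles


def average_profiles(profiles: Sequence[RadialProfile]) -> RadialProfile:
    """Per-bin mean and sample standard deviation across replicate profiles
    (identical binning and timepoint label required)."""
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if (len(p.bin_centers) != len(first.bin_centers)
                or not np.allclose(p.bin_centers, first.bin_centers)):
            raise ValueError("replicate profiles have mismatched bins")
        if p.timepoint_label != first.timepoint_label:
            raise ValueError("replicate profiles have mismatched timepoints")
    stack = np.vstack([p.mean_intensity for p in profiles])
    sd = (np.std(stack, axis=0, ddof=1) if len(profiles) > 1
          else np.zeros(stack.shape[1]))
    return dataclasses.replace(
        first,
        mean_intensity=stack.mean(axis=0),
        sd_intensity=sd,
        counts=np.full(stack.shape[1], len(profiles)),
        frame_index=None,
    )
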
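"""ROI trace extraction and the FRAP correction/normalization chain.

The chain applied to the bleach-ROI trace ``I`` with background ``I_b`` and
same-cell reference ``I_r`` is:

1. photobleach correction anchored to the pre-bleach reference mean::

       I_c[k] = (I[k] - I_b[k]) * mean_pre(I_r - I_b) / (I_r[k] - I_b[k])

2. pre-bleach normalization: ``I_cn[k] = I_c[k] / mean_pre(I_c)``
3. post-bleach renormalization with ``b`` the first post-bleach frame::

       I_dcn[k] = (I_cn[k] - I_cn[b]) / (1 - I_cn[b])

The final recovery level is a tail mean of ``I_dcn`` and the half-recovery
time is located by the first crossing of half that level on a lightly
smoothed curve (the literal max-below/min-above rule is available as an
option).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Union

import numpy as np
from matplotlib.path import Path as _MplPath

from .synthetic import ImageSeries, SimulationConfig

__all__ = [
    "DiscRoi",
    "PolygonRoi",
    "RoiSet",
    "RecoveryCurve",
    "FrapResult",
    "default_roiset",
    "extract_traces",
    "correct_photobleach",
    "normalize_prebleach",
    "renormalize_postbleach",
    "final_recovery",
    "half_recovery_time",
    "analyze_frap",
]


# ---------------------------------------------------------------------------
# regions of interest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscRoi:
    """Disc region; ``center`` is (x, y) in micrometres from the top-left
    pixel centre."""

    center: tuple[float, float]
    radius: float

    def rasterize(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        ny, nx = shape
        cx, cy = self.center
        y = np.arange(ny) * pixel_size
        x = np.arange(nx) * pixel_size
        r = np.hypot(y[:, None] - cy, x[None, :] - cx)
        return r <= self.radius

    def to_dict(self) -> dict[str, Any]:
        return {"type": "disc", "center": list(self.center), "radius": self.radius}


@dataclass(frozen=True)
class PolygonRoi:
    """Polygon region; vertices are (x, y) in micrometres.  Membership is by
    pixel centre."""

    vertices: tuple[tuple[float, float], ...]

    def rasterize(self, shape: tuple[int, int], pixel_size: float) -> np.ndarray:
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        pts = np.column_stack([xx.ravel() * pixel_size, yy.ravel() * pixel_size])
        path = _MplPath(np.asarray(self.vertices, dtype=float))
        return path.contains_points(pts).reshape(ny, nx)

    def to_dict(self) -> dict[str, Any]:
        return {"type": "polygon", "vertices": [list(v) for v in self.vertices]}


Roi = Union[DiscRoi, PolygonRoi]


def roi_from_dict(d: dict[str, Any]) -> Roi:
    kind = d.get("type", "disc")
    if kind == "disc":
        return DiscRoi(center=tuple(d["center"]), radius=float(d["radius"]))
    if kind == "polygon":
        return PolygonRoi(vertices=tuple(tuple(v) for v in d["vertices"]))
    raise ValueError(f"unknown ROI type {kind!r}")


@dataclass(frozen=True)
class RoiSet:
    """Bleach disc + same-cell reference + cell-free background regions."""

    bleach_disc: DiscRoi
    reference_region: Roi
    background_region: Roi

    def masks(self, shape: tuple[int, int], pixel_size: float,
              min_pixels: int = 20) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        out = []
        for name, roi in (("bleach_disc", self.bleach_disc),
                          ("reference_region", self.reference_region),
                          ("background_region", self.background_region)):
            m = roi.rasterize(shape, pixel_size)
            if m.sum() < min_pixels:
                raise ValueError(
                    f"{name} rasterizes to {int(m.sum())} pixels "
                    f"(< {min_pixels}) on a {shape} grid")
            out.append(m)
        b, r, g = out
        if (b & r).any() or (b & g).any() or (r & g).any():
            raise ValueError("ROIs overlap; regions must be pairwise disjoint")
        return b, r, g

    def to_dict(self) -> dict[str, Any]:
        return {
            "bleach_disc": self.bleach_disc.to_dict(),
            "reference_region": self.reference_region.to_dict(),
            "background_region": self.background_region.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RoiSet":
        bd = roi_from_dict(d["bleach_disc"])
        if not isinstance(bd, DiscRoi):
            raise ValueError("bleach_disc must be a disc ROI")
        return cls(
            bleach_disc=bd,
            reference_region=roi_from_dict(d["reference_region"]),
            background_region=roi_from_dict(d["background_region"]),
        )


def default_roiset(config: SimulationConfig) -> RoiSet:
    """ROI set matched to a simulated acquisition: the bleach disc itself, a
    reference disc on the opposite side of the field, and a background disc
    inside the cell-free corner."""
    ny, nx = config.grid_shape
    ps = config.pixel_size
    cx, cy = config.resolved_bleach_center()
    xmax, ymax = (nx - 1) * ps, (ny - 1) * ps
    ref_r = min(1.5, config.bleach_radius)
    ref_x = min(cx + config.bleach_radius + 2.0 + ref_r, xmax - ref_r - 0.2)
    ref = DiscRoi(center=(ref_x, cy), radius=ref_r)
    corner = config.cell_free_size
    bg_r = max(0.35 * corner, 5 * ps)
    bg = DiscRoi(center=(0.45 * corner, 0.45 * corner), radius=bg_r)
    return RoiSet(bleach_disc=DiscRoi(center=(cx, cy), radius=config.bleach_radius),
                  reference_region=ref, background_region=bg)


# ---------------------------------------------------------------------------
# recovery curves
# ---------------------------------------------------------------------------


@dataclass
class RecoveryCurve:
    """Raw and corrected per-frame traces of one FRAP run.

    Times are seconds with 0 at the first post-bleach frame (index
    ``bleach_index``); pre-bleach frames carry negative times.
    """

    t: np.ndarray
    I: np.ndarray
    I_b: np.ndarray
    I_r: np.ndarray
    n_prebleach: int
    bleach_index: int
    I_c: np.ndarray | None = None
    I_cn: np.ndarray | None = None
    I_dcn: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("I", "I_b", "I_r", "I_c", "I_cn", "I_dcn"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"trace {name} has length {len(v)}, expected {n}")
        if not 0 < self.bleach_index < n:
            raise ValueError("bleach_index outside curve")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def _pre(self, trace: np.ndarray) -> np.ndarray:
        return trace[: self.n_prebleach]


@dataclass
class FrapResult:
    """Headline FRAP measurements: final level, half-recovery time, fractions
    (percent)."""

    final_level: float
    tau_a: float
    tau_b: float
    tau_half: float
    mobile_fraction: float
    immobile_fraction: float
    smoothing_window: int
    tail_frames: int
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def extract_traces(series: ImageSeries, rois: RoiSet) -> RecoveryCurve:
    """Per-frame arithmetic means over the three ROIs (pixel-centre
    membership)."""
    b_mask, r_mask, g_mask = rois.masks(series.shape, series.pixel_size)
    frames = series.frames.reshape(series.n_frames, -1).astype(float)
    traces = [frames[:, m.ravel()].mean(axis=1) for m in (b_mask, r_mask, g_mask)]
    return RecoveryCurve(
        t=series.times(),
        I=traces[0], I_r=traces[1], I_b=traces[2],
        n_prebleach=series.bleach_frame_index,
        bleach_index=series.bleach_frame_index,
    )


def correct_photobleach(curve: RecoveryCurve) -> RecoveryCurve:
    """Background-subtract and correct monitor bleaching by the reference
    trace, anchored to the pre-bleach reference mean."""
    ref = curve.I_r - curve.I_b
    bad = np.nonzero(ref <= 0)[0]
    if bad.size:
        raise ValueError(
            f"reference minus background is non-positive at frame {bad[0]}")
    pre_ref = curve._pre(ref).mean()
    i_c = (curve.I - curve.I_b) * pre_ref / ref
    return dataclasses.replace(curve, I_c=i_c)


def normalize_prebleach(curve: RecoveryCurve) -> RecoveryCurve:
    if curve.I_c is None:
        raise ValueError("run correct_photobleach first")
    pre = curve._pre(curve.I_c).mean()
    if pre <= 0:
        raise ValueError(f"non-positive pre-bleach corrected mean ({pre:.4g})")
    return dataclasses.replace(curve, I_cn=curve.I_c / pre)


def renormalize_postbleach(curve: RecoveryCurve) -> RecoveryCurve:
    if curve.I_cn is None:
        raise ValueError("run normalize_prebleach first")
    i0 = curve.I_cn[curve.bleach_index]
    if i0 >= 1.0:
        raise ValueError(
            f"no bleach detected: normalized intensity at the first "
            f"post-bleach frame is {i0:.4g} >= 1")
    return dataclasses.replace(curve, I_dcn=(curve.I_cn - i0) / (1.0 - i0))


def final_recovery(curve: RecoveryCurve, tail_frames: int = 10) -> float:
    """Mean of the doubly normalized trace over the last ``tail_frames``
    frames (1 = the literal last measurement)."""
    if curve.I_dcn is None:
        raise ValueError("run renormalize_postbleach first")
    if tail_frames < 1:
        raise ValueError("tail_frames must be >= 1")
    n_post = curve.n_frames - curve.bleach_index
    if tail_frames > n_post:
        raise ValueError(
            f"tail_frames {tail_frames} exceeds post-bleach length {n_post}")
    return float(curve.I_dcn[-tail_frames:].mean())


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    padded = np.pad(values.astype(float), half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def half_recovery_time(curve: RecoveryCurve, final_level: float | None = None,
                       smoothing_window: int = 11, tail_frames: int = 10,
                       method: str = "interpolate") -> tuple[float, float, float]:
    """Locate the half-recovery time on the smoothed post-bleach trace.

    ``tau_b`` is the time of the first smoothed sample at or above half the
    final level, ``tau_a`` the time of the preceding sample; ``tau_half``
    interpolates linearly between them (``method='midpoint'`` averages them,
    ``method='literal'`` applies the max-below/min-above rule verbatim).
    Returns ``(tau_a, tau_b, tau_half)``, all NaN for a non-recovering curve.
    """
    if curve.I_dcn is None:
        raise ValueError("run renormalize_postbleach first")
    if final_level is None:
        final_level = final_recovery(curve, tail_frames)
    if final_level <= 0:
        nan = float("nan")
        return (nan, nan, nan)
    post = curve.I_dcn[curve.bleach_index:]
    t_post = curve.t[curve.bleach_index:]
    smoothed = _smooth(post, smoothing_window)
    level = final_level / 2.0

    if method == "literal":
        below = np.nonzero(smoothed < level)[0]
        above = np.nonzero(smoothed > level)[0]
        if below.size == 0:
            return (0.0, 0.0, 0.0)
        if above.size == 0:
            raise ValueError("curve never exceeds half the final level")
        ia = below[np.argmax(smoothed[below])]
        ib = above[np.argmin(smoothed[above])]
        tau_a, tau_b = float(t_post[ia]), float(t_post[ib])
        return (tau_a, tau_b, 0.5 * (tau_a + tau_b))

    crossings = np.nonzero(smoothed >= level)[0]
    if crossings.size == 0:
        raise ValueError(
            f"smoothed curve never reaches half the final level ({level:.4g}); "
            "inconsistent with the final-level estimate")
    ib = int(crossings[0])
    if ib == 0:
        return (0.0, 0.0, 0.0)
    tau_a, tau_b = float(t_post[ib - 1]), float(t_post[ib])
    va, vb = smoothed[ib - 1], smoothed[ib]
    if method == "midpoint" or vb <= va:
        return (tau_a, tau_b, 0.5 * (tau_a + tau_b))
    frac = (level - va) / (vb - va)
    return (tau_a, tau_b, tau_a + frac * (tau_b - tau_a))


def analyze_frap(series: ImageSeries, rois: RoiSet, *, tail_frames: int = 10,
                 smoothing_window: int = 11,
                 method: str = "interpolate") -> FrapResult:
    """Full chain: traces -> correction -> double normalization -> final
    level + half time.  Mobile fraction is the final level clipped to [0, 1],
    in percent."""
    curve = extract_traces(series, rois)
    curve = correct_photobleach(curve)
    curve = normalize_prebleach(curve)
    curve = renormalize_postbleach(curve)
    i_f = final_recovery(curve, tail_frames)
    tau_a, tau_b, tau_half = half_recovery_time(
        curve, i_f, smoothing_window, tail_frames, method)
    mobile = 100.0 * min(max(i_f, 0.0), 1.0)
    return FrapResult(
        final_level=i_f,
        tau_a=tau_a, tau_b=tau_b, tau_half=tau_half,
        mobile_fraction=mobile,
        immobile_fraction=100.0 - mobile,
        smoothing_window=smoothing_window,
        tail_frames=tail_frames,
        provenance={
            "rois": rois.to_dict(),
            "pixel_size": series.pixel_size,
            "frame_interval": series.frame_interval,
            "bleach_frame_index": series.bleach_frame_index,
            "method": method,
        },
    )


def curve_to_frame(curve: RecoveryCurve) -> "pandas_frame":
    """Tidy per-frame table of all traces (columns t, I, I_b, I_r, I_c, I_cn,
    I_dcn)."""
    import pandas as pd

    data = {"t": curve.t, "I": curve.I, "I_b": curve.I_b, "I_r": curve.I_r}
    for name in ("I_c", "I_cn", "I_dcn"):
        v = getattr(curve, name)
        if v is not None:
            data[name] = v
    return pd.DataFrame(data)
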
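"""Stack/sidecar readers and writers, run manifests, and batch experiments."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .quant import RoiSet, analyze_frap, default_roiset
from .synthetic import ImageSeries, SimulationConfig, make_preset, simulate_frap

__all__ = [
    "write_stack",
    "read_stack",
    "sidecar_path",
    "load_roiset",
    "save_roiset",
    "write_manifest",
    "run_recovery_experiment",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(series: ImageSeries, path: str | Path,
                bit_depth: int = 16) -> Path:
    """Write an ImageJ-compatible multi-page TIFF plus a JSON sidecar with
    calibration, config and ground truth.  Returns the sidecar path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bit_depth == 16:
        data = np.clip(np.rint(series.frames), 0, 65535).astype(np.uint16)
    elif bit_depth == 8:
        data = np.clip(np.rint(series.frames), 0, 255).astype(np.uint8)
    else:
        data = series.frames.astype(np.float32)
    tifffile.imwrite(
        path, data, imagej=(bit_depth in (8, 16)),
        resolution=(1.0 / series.pixel_size, 1.0 / series.pixel_size),
        metadata={"axes": "TYX", "unit": "um",
                  "finterval": series.frame_interval},
    )
    side = sidecar_path(path)
    payload = {
        "pixel_size": series.pixel_size,
        "frame_interval": series.frame_interval,
        "bleach_frame_index": series.bleach_frame_index,
        "bit_depth": bit_depth,
        "frapkit_version": __version__,
    }
    payload.update({k: v for k, v in series.metadata.items()})
    side.write_text(json.dumps(payload, indent=2, default=_json_default))
    return side


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_stack(path: str | Path, *, pixel_size: float | None = None,
               frame_interval: float | None = None,
               bleach_frame_index: int | None = None) -> ImageSeries:
    """Read a TIFF stack; calibration comes from the JSON sidecar unless
    overridden by the explicit keyword arguments."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) stack, got shape {frames.shape}")
    meta: dict[str, Any] = {}
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size")
    frame_interval = (frame_interval if frame_interval is not None
                      else meta.get("frame_interval"))
    bleach_frame_index = (bleach_frame_index if bleach_frame_index is not None
                          else meta.get("bleach_frame_index"))
    missing = [n for n, v in (("pixel_size", pixel_size),
                              ("frame_interval", frame_interval),
                              ("bleach_frame_index", bleach_frame_index))
               if v is None]
    if missing:
        raise ValueError(
            f"missing calibration {missing}: provide a sidecar JSON next to "
            f"{path.name} or pass the values explicitly")
    return ImageSeries(
        frames=frames.astype(np.float32),
        pixel_size=float(pixel_size),
        frame_interval=float(frame_interval),
        bleach_frame_index=int(bleach_frame_index),
        metadata=meta,
    )


def load_roiset(path: str | Path) -> RoiSet:
    """Read an ROI set from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RoiSet.from_dict(data)


def save_roiset(rois: RoiSet, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(rois.to_dict()))


def write_manifest(out_dir: str | Path, command: str,
                   resolved: dict[str, Any]) -> Path:
    """Echo the fully resolved configuration of a run for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"command": command, "frapkit_version": __version__}
    manifest.update(resolved)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return p


def run_recovery_experiment(preset: str, n_seeds: int = 5,
                            out_dir: str | Path | None = None,
                            base_seed: int = 0, calibrate: bool = True,
                            config: SimulationConfig | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse ``n_seeds`` replicate stacks of one preset.

    Returns (per-seed table, one-row aggregate with mean and sd of the mobile
    fraction and half-recovery time); writes both as CSV when ``out_dir`` is
    given.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if config is None:
        config = make_preset(preset, calibrate=calibrate)
    rows = []
    for i in range(n_seeds):
        cfg = dataclasses.replace(config, seed=base_seed + i)
        series, truth = simulate_frap(cfg)
        res = analyze_frap(series, default_roiset(cfg))
        rows.append({
            "preset": preset, "seed": cfg.seed,
            "mobile_fraction_pct": res.mobile_fraction,
            "tau_half_s": res.tau_half,
            "final_level": res.final_level,
            "tau_a_s": res.tau_a, "tau_b_s": res.tau_b,
            "truth_mobile_fraction": truth.mobile_fraction,
            "truth_diffusion_um2_s": truth.diffusion_coeff,
        })
    per_seed = pd.DataFrame(rows)
    agg = pd.DataFrame([{
        "preset": preset,
        "n_seeds": n_seeds,
        "mobile_fraction_mean_pct": per_seed["mobile_fraction_pct"].mean(),
        "mobile_fraction_sd_pct": (per_seed["mobile_fraction_pct"].std(ddof=1)
                                   if n_seeds > 1 else 0.0),
        "tau_half_mean_s": per_seed["tau_half_s"].mean(),
        "tau_half_sd_s": (per_seed["tau_half_s"].std(ddof=1)
                          if n_seeds > 1 else 0.0),
    }])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_seed.to_csv(out_dir / f"{preset}_per_seed.csv", index=False)
        agg.to_csv(out_dir / f"{preset}_aggregate.csv", index=False)
        write_manifest(out_dir, "recover", {
            "preset": preset, "n_seeds": n_seeds, "base_seed": base_seed,
            "config": config.to_dict(),
        })
    return per_seed, agg
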
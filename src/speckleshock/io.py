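"""File formats: multi-page TIFF speckle stacks with JSON metadata
sidecars, phantom manifests, cohort / ROI-series / RR CSVs, evaluation
reports, and the run manifest.

All CSVs are comma-separated UTF-8 with a mandatory header row and '.'
decimals.  Timestamps are seconds from recording start; pixel
coordinates are 0-based (x, y).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from speckleshock.contrast import PerfusionMap
from speckleshock.roi import RoiSeries, RoiSpec
from speckleshock.simulate import AcquisitionConfig, FlowPhantom, RRSeries, SpeckleStack

__all__ = [
    "read_stack",
    "write_stack",
    "write_phantom",
    "read_phantom",
    "write_cohort",
    "read_cohort",
    "write_rr_series",
    "read_rr_series",
    "write_roi_series",
    "read_roi_series",
    "write_roi_spec",
    "read_roi_spec",
    "write_outputs",
]

_STACK_KEYS = ("exposure_time", "frame_rate", "wavelength", "scale")


def write_stack(stack: SpeckleStack, path, metadata_path=None, scale: float | None = None) -> None:
    """Write a stack as multi-page 16-bit TIFF plus a JSON sidecar.

    ``scale`` converts float intensities to integer counts; by default
    the dynamic range is mapped so the maximum lands at ~90% of the
    16-bit range.
    """
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    peak = float(stack.frames.max())
    if scale is None:
        scale = (0.9 * 65535.0 / peak) if peak > 0 else 1.0
    data = np.clip(np.round(stack.frames * scale), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    cfg = stack.config
    meta = {
        "exposure_time": cfg.exposure_time,
        "frame_rate": cfg.frame_rate,
        "wavelength": cfg.wavelength,
        "sensor_shape": list(stack.frame_shape),
        "pixel_pitch": cfg.pixel_pitch,
        "bit_depth": 16,
        "n_frames": stack.n_frames,
        "scale": scale,
        "timestamps": stack.timestamps.tolist(),
    }
    metadata_path.write_text(json.dumps(meta, indent=2))


def read_stack(path, metadata_path=None) -> SpeckleStack:
    """Read a multi-page TIFF stack with its JSON metadata sidecar."""
    path = Path(path)
    metadata_path = Path(metadata_path) if metadata_path else path.with_suffix(".json")
    if not metadata_path.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {metadata_path}; required keys: "
            + ", ".join(_STACK_KEYS)
        )
    meta = json.loads(metadata_path.read_text())
    missing = [k for k in _STACK_KEYS if k not in meta]
    if missing:
        raise ValueError(f"metadata missing required keys: {missing}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - exercised with a bad file
        raise ValueError(f"corrupt or unreadable TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if "sensor_shape" in meta and list(data.shape[1:]) != list(meta["sensor_shape"]):
        raise ValueError(
            f"frame shape {data.shape[1:]} does not match metadata "
            f"{tuple(meta['sensor_shape'])}"
        )
    if "n_frames" in meta and data.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"frame count {data.shape[0]} does not match metadata {meta['n_frames']}"
        )
    config = AcquisitionConfig(
        exposure_time=meta["exposure_time"],
        frame_rate=meta["frame_rate"],
        wavelength=meta["wavelength"],
        sensor_shape=tuple(meta.get("sensor_shape", data.shape[1:])),
        pixel_pitch=meta.get("pixel_pitch", 200.0 / 1280.0),
        bit_depth=meta.get("bit_depth", 16),
    )
    ts = np.asarray(
        meta.get("timestamps", np.arange(data.shape[0]) / meta["frame_rate"])
    )
    frames = data.astype(float) / meta["scale"]
    return SpeckleStack(frames=frames, config=config, timestamps=ts)


def write_phantom(phantom: FlowPhantom, tau_path, manifest_path=None) -> None:
    """Store a phantom as a 32-bit float TIFF (seconds) plus a JSON
    manifest {label, beta, tau_map_file, shape}."""
    tau_path = Path(tau_path)
    manifest_path = Path(manifest_path) if manifest_path else tau_path.with_suffix(".json")
    tifffile.imwrite(tau_path, phantom.tau_map.astype(np.float32))
    manifest_path.write_text(
        json.dumps(
            {
                "label": phantom.label,
                "beta": phantom.beta,
                "tau_map_file": tau_path.name,
                "shape": list(phantom.shape),
            },
            indent=2,
        )
    )


def read_phantom(manifest_path) -> FlowPhantom:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    tau = tifffile.imread(manifest_path.parent / meta["tau_map_file"]).astype(float)
    return FlowPhantom(tau_map=tau, beta=meta["beta"], label=meta.get("label", ""))


_COHORT_COLUMNS = [
    "subject_id", "group", "SBP", "DBP", "MAP", "HR", "RR", "SpO2", "BT",
    "SI", "lactate", "ROI1", "ROI2", "ROI_diff",
]


def write_cohort(table: pd.DataFrame, path) -> None:
    table.loc[:, _COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_rr_series(rr: RRSeries, path) -> None:
    pd.DataFrame(
        {"index": np.arange(len(rr)), "rr_ms": rr.rr_intervals}
    ).to_csv(path, index=False)


def read_rr_series(path) -> RRSeries:
    df = pd.read_csv(path)
    if "rr_ms" not in df.columns:
        raise ValueError("RR CSV must have an 'rr_ms' column")
    return RRSeries(rr_intervals=df["rr_ms"].to_numpy(float))


def write_roi_series(series: RoiSeries, path) -> None:
    t = series.timestamps - series.timestamps[0]
    diff = series.roi1_values - series.roi2_values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = diff / series.roi2_values
    pd.DataFrame(
        {
            "time_s": t,
            "roi1": series.roi1_values,
            "roi2": series.roi2_values,
            "roi_diff": diff,
            "roi_ratio": ratio,
        }
    ).to_csv(path, index=False)


def read_roi_series(path) -> RoiSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "roi1", "roi2"):
        if col not in df.columns:
            raise ValueError(f"ROI series CSV missing column {col!r}")
    return RoiSeries(
        timestamps=df["time_s"].to_numpy(float),
        roi1_values=df["roi1"].to_numpy(float),
        roi2_values=df["roi2"].to_numpy(float),
    )


def write_roi_spec(spec: RoiSpec, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "label": spec.label,
                "cx": spec.center[0],
                "cy": spec.center[1],
                "radius": spec.radius,
                "units": spec.units,
            },
            indent=2,
        )
    )


def read_roi_spec(path) -> RoiSpec:
    meta = json.loads(Path(path).read_text())
    return RoiSpec(
        label=meta["label"],
        center=(meta["cx"], meta["cy"]),
        radius=meta["radius"],
        units=meta.get("units", "px"),
    )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_outputs(results: dict, output_dir, config: dict | None = None, seed=None) -> list[Path]:
    """Write a result bundle with deterministic file names.

    Recognized keys in ``results``: ``roi_series`` (RoiSeries),
    ``evaluation`` (DataFrame), ``perfusion_maps`` (list of
    PerfusionMap), ``cohort`` (DataFrame), ``summary`` (DataFrame).
    A JSON ``manifest.json`` with the config hash, seed, and file list
    is always written.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "roi_series" in results:
        p = output_dir / "roi_series.csv"
        write_roi_series(results["roi_series"], p)
        written.append(p)
    if "evaluation" in results:
        p = output_dir / "evaluation.csv"
        results["evaluation"].to_csv(p, index=False)
        written.append(p)
    if "cohort" in results:
        p = output_dir / "cohort.csv"
        write_cohort(results["cohort"], p)
        written.append(p)
    if "summary" in results:
        p = output_dir / "summary.csv"
        results["summary"].to_csv(p, index=False)
        written.append(p)
    if "perfusion_maps" in results:
        maps: list[PerfusionMap] = results["perfusion_maps"]
        p = output_dir / "perfusion.tif"
        tifffile.imwrite(
            p, np.stack([m.P for m in maps]).astype(np.float32),
            photometric="minisblack",
        )
        written.append(p)

    manifest = {
        "config_hash": _config_hash(config or {}),
        "seed": seed,
        "files": [p.name for p in written],
    }
    mp = output_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(mp)
    return written
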
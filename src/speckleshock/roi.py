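"""Dual-ROI extraction from perfusion-map sequences and the derived
shock statistics.

Two circular regions of interest are tracked over a recording: ROI1 on
the fingernail and ROI2 on the fingertip skin.  The shock statistic is
the aggregate difference ``roi_diff = agg(ROI1) - agg(ROI2)`` and its
gain-invariant normalization ``roi_ratio = roi_diff / agg(ROI2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from speckleshock.contrast import PerfusionMap

__all__ = [
    "RoiSpec",
    "RoiSeries",
    "ShockMetrics",
    "circular_mask",
    "extract_roi_series",
    "compute_shock_metrics",
]


@dataclass(frozen=True)
class RoiSpec:
    """A circular ROI: center (x, y) in 0-based pixel coordinates and a
    radius in pixels or millimeters (``units``)."""

    label: str
    center: tuple[float, float]  # (x, y), px
    radius: float
    units: str = "px"  # "px" or "mm"
    anatomical_hint: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.units not in ("px", "mm"):
            raise ValueError("units must be 'px' or 'mm'")

    def radius_px(self, pixel_pitch: float | None = None) -> float:
        if self.units == "px":
            return self.radius
        if pixel_pitch is None or pixel_pitch <= 0:
            raise ValueError("pixel_pitch (mm/px) required for mm radii")
        return self.radius / pixel_pitch


@dataclass(frozen=True)
class RoiSeries:
    """Timestamped ROI1/ROI2 perfusion values for one recording."""

    timestamps: np.ndarray  # seconds
    roi1_values: np.ndarray
    roi2_values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v1 = np.asarray(self.roi1_values, dtype=float)
        v2 = np.asarray(self.roi2_values, dtype=float)
        if not (t.shape == v1.shape == v2.shape):
            raise ValueError("timestamps and ROI series must have equal length")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "roi1_values", v1)
        object.__setattr__(self, "roi2_values", v2)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class ShockMetrics:
    roi_diff: float
    roi_ratio: float
    window_s: float
    aggregation: str
    n_samples: int


def circular_mask(
    spec: RoiSpec,
    shape: tuple[int, int],
    pixel_pitch: float | None = None,
    allow_clipping: bool = True,
) -> np.ndarray:
    """Boolean disc mask: a pixel is included iff its center lies within
    the radius of the ROI center (Euclidean, 0-based pixel centers)."""
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    r = spec.radius_px(pixel_pitch)
    cx, cy = spec.center
    if not allow_clipping:
        if cx - r < -0.5 or cx + r > w - 0.5 or cy - r < -0.5 or cy + r > h - 0.5:
            raise ValueError(f"ROI {spec.label!r} extends outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    if not mask.any():
        raise ValueError(f"ROI {spec.label!r} covers no pixels")
    return mask


def extract_roi_series(
    maps: Sequence[PerfusionMap],
    roi1: RoiSpec,
    roi2: RoiSpec,
    pixel_pitch: float | None = None,
) -> RoiSeries:
    """Mean perfusion inside each ROI at every timestamp.

    Invalid pixels are excluded from the mean; a frame in which an ROI
    has no valid pixel yields NaN for that ROI.  Overlapping ROIs are
    rejected (the nail and skin discs must be disjoint).
    """
    if not maps:
        raise ValueError("no perfusion maps given")
    shape = maps[0].P.shape
    m1 = circular_mask(roi1, shape, pixel_pitch)
    m2 = circular_mask(roi2, shape, pixel_pitch)
    if np.any(m1 & m2):
        raise ValueError("ROI1 and ROI2 masks overlap")

    t = np.empty(len(maps))
    v1 = np.empty(len(maps))
    v2 = np.empty(len(maps))
    for i, pm in enumerate(maps):
        t[i] = pm.timestamp
        for mask, out in ((m1, v1), (m2, v2)):
            sel = mask & pm.valid_mask
            out[i] = np.mean(pm.P[sel]) if sel.any() else np.nan
    return RoiSeries(timestamps=t, roi1_values=v1, roi2_values=v2)


def compute_shock_metrics(
    series: RoiSeries,
    window_s: float = 60.0,
    aggregation: str = "mean",
    offset_s: float = 0.0,
) -> ShockMetrics:
    """Aggregate the ROI series over a window and derive the shock
    statistics.

    Over ``[offset_s, offset_s + window_s)`` seconds from the start:
    ``roi_diff = agg(ROI1) - agg(ROI2)`` and
    ``roi_ratio = roi_diff / agg(ROI2)``.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    t = series.timestamps - series.timestamps[0]
    sel = (t >= offset_s) & (t < offset_s + window_s + 1e-9)
    sel &= ~np.isnan(series.roi1_values) & ~np.isnan(series.roi2_values)
    n = int(np.count_nonzero(sel))
    if n < 3:
        raise ValueError(f"only {n} samples in the {window_s}-s window (need >= 3)")
    agg = np.mean if aggregation == "mean" else np.median
    a1 = float(agg(series.roi1_values[sel]))
    a2 = float(agg(series.roi2_values[sel]))
    roi_diff = a1 - a2
    if a2 <= 0:
        raise ValueError("aggregate ROI2 is non-positive; ratio undefined")
    return ShockMetrics(
        roi_diff=roi_diff,
        roi_ratio=roi_diff / a2,
        window_s=window_s,
        aggregation=aggregation,
        n_samples=n,
    )
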
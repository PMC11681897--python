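"""Spatial and temporal speckle contrast, perfusion index maps, and
rate-decimated stream processing.

Contrast is the ratio of the population standard deviation of the
intensity to its mean over a sliding window (``K = sigma / <I>``); the
perfusion index is the flow-proportional inverse square ``P = 1/K**2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from speckleshock.simulate import SpeckleStack

__all__ = [
    "ContrastMap",
    "PerfusionMap",
    "spatial_contrast",
    "perfusion_index",
    "temporal_contrast",
    "stream_process",
]


@dataclass(frozen=True)
class ContrastMap:
    """Per-pixel speckle contrast with a validity mask.

    Border pixels without a full window are invalid; so are pixels whose
    window mean is zero.
    """

    K: np.ndarray
    valid_mask: np.ndarray
    window: int
    frame_index: int = 0

    def mean_valid(self) -> float:
        """Spatial mean of K over valid pixels."""
        return float(np.mean(self.K[self.valid_mask]))


@dataclass(frozen=True)
class PerfusionMap:
    """Per-pixel perfusion index 1/K**2 with mask and clamp record."""

    P: np.ndarray
    valid_mask: np.ndarray
    k_floor: float
    frame_index: int = 0
    timestamp: float = 0.0

    def mean_valid(self) -> float:
        return float(np.mean(self.P[self.valid_mask]))


def _check_window(window: int, shape: tuple[int, int]) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(shape):
        raise ValueError("window larger than the frame")


def spatial_contrast(frame: np.ndarray, window: int = 7, frame_index: int = 0) -> ContrastMap:
    """Sliding-window spatial contrast K = population sigma / mean.

    Pixels whose window mean is zero are masked rather than propagated
    as NaN; border pixels lacking a full ``window x window``
    neighborhood are masked.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if np.any(frame < 0):
        raise ValueError("frame intensities must be non-negative")
    _check_window(window, frame.shape)

    mean = uniform_filter(frame, size=window, mode="constant")
    meansq = uniform_filter(frame * frame, size=window, mode="constant")
    var = np.maximum(meansq - mean * mean, 0.0)

    h, w = frame.shape
    half = window // 2
    valid = np.zeros((h, w), dtype=bool)
    valid[half : h - half, half : w - half] = True

    nonzero = mean > 0
    K = np.zeros_like(frame)
    np.divide(np.sqrt(var), mean, out=K, where=nonzero)
    valid &= nonzero
    if not np.any(valid):
        warnings.warn("no valid pixels (all-zero frame?)", RuntimeWarning, stacklevel=2)
    return ContrastMap(K=K, valid_mask=valid, window=window, frame_index=frame_index)


def perfusion_index(kmap: ContrastMap, k_floor: float = 0.01) -> PerfusionMap:
    """Perfusion index P = 1 / max(K, k_floor)**2 on valid pixels."""
    if k_floor <= 0:
        raise ValueError("k_floor must be positive")
    k = np.maximum(kmap.K, k_floor)
    P = np.zeros_like(k)
    np.divide(1.0, k * k, out=P, where=kmap.valid_mask)
    return PerfusionMap(
        P=P, valid_mask=kmap.valid_mask.copy(), k_floor=k_floor,
        frame_index=kmap.frame_index,
    )


def temporal_contrast(stack: SpeckleStack, window_frames: int) -> list[ContrastMap]:
    """Per-pixel contrast over a sliding temporal window of frames.

    Acts as an independent cross-check of the spatial estimator: on
    ergodic simulated speckle the two agree.  Returns one map per window
    start position, indexed by the first frame of the window.
    """
    if window_frames < 5:
        raise ValueError("window_frames must be >= 5")
    if window_frames > stack.n_frames:
        raise ValueError("window_frames exceeds the number of frames")
    frames = stack.frames
    out = []
    for start in range(stack.n_frames - window_frames + 1):
        block = frames[start : start + window_frames]
        mean = block.mean(axis=0)
        sigma = block.std(axis=0)  # population SD over time
        valid = mean > 0
        K = np.zeros_like(mean)
        np.divide(sigma, mean, out=K, where=valid)
        out.append(
            ContrastMap(K=K, valid_mask=valid, window=window_frames, frame_index=start)
        )
    return out


def stream_process(
    stack: SpeckleStack,
    window: int = 7,
    output_rate: float = 2.7,
    k_floor: float = 0.01,
) -> list[PerfusionMap]:
    """Compute per-frame perfusion maps and decimate to ``output_rate``.

    The non-integer 15 fps -> 2.7 Hz ratio is resolved by averaging the
    per-frame perfusion maps falling in consecutive ``1/output_rate``-s
    bins (5 or 6 frames per bin at the defaults).  One map is emitted
    per non-empty bin, stamped with the mean frame time of the bin.
    """
    if output_rate <= 0:
        raise ValueError("output_rate must be positive")
    if output_rate > stack.config.frame_rate + 1e-9:
        raise ValueError("output_rate cannot exceed the input frame rate")

    pmaps = [
        perfusion_index(spatial_contrast(stack.frames[i], window, frame_index=i), k_floor)
        for i in range(stack.n_frames)
    ]
    bins = np.floor(stack.timestamps * output_rate + 1e-9).astype(int)
    out: list[PerfusionMap] = []
    for b in np.unique(bins):
        members = [pmaps[i] for i in np.nonzero(bins == b)[0]]
        times = stack.timestamps[bins == b]
        valid = members[0].valid_mask
        for m in members[1:]:
            valid = valid & m.valid_mask
        P = np.mean([m.P for m in members], axis=0)
        out.append(
            PerfusionMap(
                P=P, valid_mask=valid, k_floor=k_floor,
                frame_index=members[0].frame_index,
                timestamp=float(np.mean(times)),
            )
        )
    return out
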
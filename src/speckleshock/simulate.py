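"""Synthetic data generators: speckle stacks with known flow ground truth,
two-group clinical cohorts, and RR-interval series.

The speckle simulator produces raw intensity frames whose windowed
contrast statistics follow the single-exposure contrast model for a
negative-exponential field autocorrelation ``g1(t) = exp(-t / tau_c)``
(Lorentzian spectrum).  Static regions are encoded with ``tau_c = inf``
and stay frozen across frames; their single-frame contrast squared
equals the speckle-averaging factor ``beta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AcquisitionConfig",
    "FlowPhantom",
    "SpeckleStack",
    "RRSeries",
    "DEFAULT_COHORT_PARAMS",
    "make_phantom",
    "simulate_speckle_stack",
    "simulate_cohort",
    "simulate_rr_series",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera acquisition settings.

    Defaults match a 5 ms exposure, 15 fps, 805 nm near-infrared system
    with a 1280x1024 sensor imaging a 200x150 mm field.
    """

    exposure_time: float = 0.005  # seconds
    frame_rate: float = 15.0  # Hz
    wavelength: float = 805e-9  # meters
    sensor_shape: tuple[int, int] = (1024, 1280)  # (height, width) px
    pixel_pitch: float = 200.0 / 1280.0  # mm per pixel
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.exposure_time > 1.0 / self.frame_rate + 1e-12:
            raise ValueError("exposure_time cannot exceed the frame interval")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass(frozen=True)
class FlowPhantom:
    """Ground-truth decorrelation-time map and speckle-averaging factor.

    ``tau_map`` holds the per-pixel decorrelation time in seconds with
    ``np.inf`` as the static sentinel; ``beta`` is the correction factor
    in (0, 1] that the static contrast squared should equal.
    """

    tau_map: np.ndarray
    beta: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_map, dtype=float)
        if tau.ndim != 2 or tau.size == 0:
            raise ValueError("tau_map must be a non-empty 2-D array")
        if np.any(tau <= 0) or np.any(np.isnan(tau)):
            raise ValueError("all decorrelation times must be positive (inf for static)")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        object.__setattr__(self, "tau_map", tau)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau_map.shape


@dataclass(frozen=True)
class SpeckleStack:
    """Time-ordered raw speckle frames plus acquisition metadata."""

    frames: np.ndarray  # [n_frames, height, width], non-negative
    config: AcquisitionConfig
    timestamps: np.ndarray  # seconds from start

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a [n_frames, H, W] array")
        if np.any(frames < 0):
            raise ValueError("intensities must be non-negative")
        if ts.shape != (frames.shape[0],):
            raise ValueError("timestamps must have one entry per frame")
        if frames.shape[0] > 1 and np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class RRSeries:
    """Ordered RR intervals in milliseconds."""

    rr_intervals: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_intervals, dtype=float)
        if rr.ndim != 1 or rr.size < 2:
            raise ValueError("need at least two RR intervals")
        if np.any(rr <= 0):
            raise ValueError("RR intervals must be positive")
        object.__setattr__(self, "rr_intervals", rr)

    def __len__(self) -> int:
        return self.rr_intervals.size


def make_phantom(
    kind: str,
    tau_values,
    shape: tuple[int, int] = (64, 64),
    beta: float = 1.0,
    label: str = "",
) -> FlowPhantom:
    """Build a :class:`FlowPhantom` with a prescribed tau_c layout.

    Parameters
    ----------
    kind
        ``uniform`` (single tau everywhere), ``two_region`` (left/right
        halves, emulating nail-bed vs fingertip-skin contrast), or
        ``vessel`` (slow background with a fast horizontal band).
    tau_values
        A scalar for ``uniform``; a 2-sequence ``(tau_left, tau_right)``
        for ``two_region``; a 2-sequence ``(tau_background, tau_vessel)``
        for ``vessel``.  Seconds, ``np.inf`` allowed for static.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    taus = np.atleast_1d(np.asarray(tau_values, dtype=float))
    if np.any(taus <= 0) or np.any(np.isnan(taus)):
        raise ValueError("tau values must be positive (inf for static)")

    if kind == "uniform":
        if taus.size != 1:
            raise ValueError("uniform phantom takes a single tau value")
        tau_map = np.full((h, w), taus[0])
    elif kind == "two_region":
        if taus.size != 2:
            raise ValueError("two_region phantom takes (tau_left, tau_right)")
        tau_map = np.empty((h, w))
        tau_map[:, : w // 2] = taus[0]
        tau_map[:, w // 2 :] = taus[1]
    elif kind == "vessel":
        if taus.size != 2:
            raise ValueError("vessel phantom takes (tau_background, tau_vessel)")
        tau_map = np.full((h, w), taus[0])
        half = max(h // 8, 1)
        tau_map[h // 2 - half : h // 2 + half, :] = taus[1]
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")

    return FlowPhantom(tau_map=tau_map, beta=beta, label=label or kind)


def simulate_speckle_stack(
    phantom: FlowPhantom,
    config: AcquisitionConfig | None = None,
    n_frames: int = 30,
    n_substeps: int = 32,
    seed: int | None = None,
    shot_noise_photons: float | None = None,
) -> SpeckleStack:
    """Simulate a raw speckle stack from a flow phantom.

    Per pixel, a temporally correlated circular complex Gaussian field
    with autocorrelation ``exp(-t/tau_c)`` is evolved as an AR(1) chain
    at ``n_substeps`` points spanning the exposure, and the intensity
    ``|E|**2`` is averaged over the exposure.  The chain evolves
    continuously across the inter-frame gap, so static pixels
    (``tau_c = inf``) keep the same speckle realization in every frame.

    ``beta < 1`` is emulated by mixing each pixel's intensity with the
    ensemble mean with weight ``sqrt(beta)``, calibrated so that static
    contrast squared equals ``beta``.

    Same seed, same arguments -> bit-identical output.
    """
    if config is None:
        config = AcquisitionConfig()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_substeps < 8:
        raise ValueError("n_substeps must be >= 8")
    if seed is None:
        raise ValueError("a seed is required (reproducibility contract)")

    tau = phantom.tau_map
    T = config.exposure_time
    finite = np.isfinite(tau)
    if np.any(finite):
        max_ratio = np.max(T / tau[finite])
        if max_ratio > n_substeps / 4:
            warnings.warn(
                f"T/tau_c = {max_ratio:.1f} under-resolved by {n_substeps} "
                "substeps; contrast will be biased high",
                RuntimeWarning,
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    h, w = phantom.shape
    dt = T / n_substeps
    # exp(-inf) underflows cleanly to rho=0 only for tau->0; inf tau -> rho=1.
    rho_sub = np.exp(-dt / tau)
    gap = max(1.0 / config.frame_rate - T, 0.0)
    rho_gap = np.exp(-gap / tau)

    def _cn(shape):
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2.0)

    frames = np.empty((n_frames, h, w))
    e = _cn((h, w))  # stationary start, unit mean intensity
    for i in range(n_frames):
        acc = np.abs(e) ** 2
        for _ in range(n_substeps - 1):
            e = rho_sub * e + np.sqrt(1.0 - rho_sub**2) * _cn((h, w))
            acc += np.abs(e) ** 2
        frames[i] = acc / n_substeps
        e = rho_gap * e + np.sqrt(1.0 - rho_gap**2) * _cn((h, w))

    if phantom.beta < 1.0:
        mix = np.sqrt(phantom.beta)
        frames = mix * frames + (1.0 - mix) * 1.0

    if shot_noise_photons is not None:
        if shot_noise_photons <= 0:
            raise ValueError("shot_noise_photons must be positive")
        frames = rng.poisson(frames * shot_noise_photons).astype(float) / shot_noise_photons

    timestamps = np.arange(n_frames) / config.frame_rate
    return SpeckleStack(frames=frames, config=config, timestamps=timestamps)


# Two-group cohort defaults: per-variable (study_mean, study_sd,
# control_mean, control_sd) for 20 shock patients vs 20 healthy controls.
DEFAULT_COHORT_PARAMS: dict[str, tuple[float, float, float | None, float | None]] = {
    "SBP": (91.9, 18.6, 127.4, 19.4),
    "DBP": (61.3, 19.1, 77.0, 11.1),
    "MAP": (71.4, 18.5, 93.8, 12.9),
    "HR": (112.9, 24.4, 76.9, 7.7),
    "RR": (21.9, 3.2, 18.7, 0.9),
    "SpO2": (94.6, 6.9, 99.2, 0.5),
    "BT": (36.8, 1.5, 36.2, 0.1),
    "lactate": (4.5, 3.8, None, None),  # not measured in controls
    "ROI1": (33674.6, 15748.0, 36319.7, 11362.2),
    "ROI2": (24656.0, 11762.1, 21681.6, 7396.1),
}

# Physiologic truncation bounds (lo, hi) applied to every draw.
_COHORT_BOUNDS: dict[str, tuple[float, float]] = {
    "SBP": (20.0, np.inf),
    "DBP": (20.0, np.inf),
    "MAP": (20.0, np.inf),
    "HR": (20.0, 250.0),
    "RR": (4.0, 60.0),
    "SpO2": (1e-6, 100.0),
    "BT": (30.0, 43.0),
    "lactate": (0.0, np.inf),
    "ROI1": (1e-6, np.inf),
    "ROI2": (1e-6, np.inf),
}


def _truncated_normal(rng, mean, sd, lo, hi, n):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_cohort(
    n_study: int = 20,
    n_control: int = 20,
    params: dict | None = None,
    seed: int | None = None,
):
    """Draw a synthetic two-group cohort table.

    Each variable is drawn from a normal truncated at physiologic
    bounds; the shock index is recomputed as HR/SBP per subject, DBP is
    truncated above at the subject's own SBP, and ROI_diff = ROI1 - ROI2
    is enforced exactly.

    Returns a :class:`pandas.DataFrame` with columns
    ``subject_id, group, SBP, DBP, MAP, HR, RR, SpO2, BT, SI, lactate,
    ROI1, ROI2, ROI_diff``.
    """
    import pandas as pd

    if n_study < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    params = dict(DEFAULT_COHORT_PARAMS if params is None else params)
    for var, (ms, ss, mc, sc) in params.items():
        for sd in (ss, sc):
            if sd is not None and sd < 0:
                raise ValueError(f"negative SD for {var}")
    for grp_idx in (0, 2):
        sbp_m = params["SBP"][grp_idx]
        dbp_m = params["DBP"][grp_idx]
        if sbp_m is not None and dbp_m is not None and sbp_m < dbp_m:
            raise ValueError("inconsistent params: SBP mean below DBP mean")

    rng = np.random.default_rng(seed)
    records = []
    for group, n, mi, si in (("study", n_study, 0, 1), ("control", n_control, 2, 3)):
        draws: dict[str, np.ndarray] = {}
        for var in ("SBP", "MAP", "HR", "RR", "SpO2", "BT", "lactate", "ROI1", "ROI2"):
            mean, sd = params[var][mi], params[var][si]
            if mean is None:
                draws[var] = np.full(n, np.nan)
                continue
            lo, hi = _COHORT_BOUNDS[var]
            draws[var] = _truncated_normal(rng, mean, sd, lo, hi, n)
        # DBP cannot exceed the subject's own SBP
        dbp_mean, dbp_sd = params["DBP"][mi], params["DBP"][si]
        lo = _COHORT_BOUNDS["DBP"][0]
        if dbp_sd == 0:
            draws["DBP"] = np.minimum(dbp_mean, draws["SBP"])
        else:
            a = (lo - dbp_mean) / dbp_sd
            b = (draws["SBP"] - dbp_mean) / dbp_sd
            draws["DBP"] = stats.truncnorm.rvs(
                a, b, loc=dbp_mean, scale=dbp_sd, size=n, random_state=rng
            )
        draws["SI"] = draws["HR"] / draws["SBP"]
        draws["ROI_diff"] = draws["ROI1"] - draws["ROI2"]
        for i in range(n):
            records.append(
                {"subject_id": f"{group[0].upper()}{i + 1:03d}", "group": group}
                | {k: draws[k][i] for k in (
                    "SBP", "DBP", "MAP", "HR", "RR", "SpO2", "BT", "SI",
                    "lactate", "ROI1", "ROI2", "ROI_diff",
                )}
            )
    return pd.DataFrame.from_records(records)


def simulate_rr_series(
    mean_rr: float,
    sd_rr: float,
    n: int,
    model: str = "iid_gaussian",
    ar_coeff: float = 0.0,
    seed: int | None = None,
) -> RRSeries:
    """Generate a synthetic RR-interval series (milliseconds).

    ``iid_gaussian`` draws independent normals; ``ar1`` draws a
    stationary AR(1) chain with marginal SD ``sd_rr`` and lag-1
    autocorrelation ``ar_coeff``.  All intervals are floored at 200 ms.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    if not -1 < ar_coeff < 1:
        raise ValueError("|ar_coeff| must be < 1")
    if sd_rr < 0:
        raise ValueError("sd_rr must be non-negative")
    if sd_rr > 0 and mean_rr <= 5 * sd_rr:
        warnings.warn(
            "mean_rr <= 5*sd_rr: truncation will distort the moments",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    if model == "iid_gaussian":
        rr = mean_rr + sd_rr * rng.standard_normal(n)
    elif model == "ar1":
        rr = np.empty(n)
        x = rng.standard_normal() * sd_rr
        innov_sd = sd_rr * np.sqrt(1.0 - ar_coeff**2)
        for i in range(n):
            rr[i] = mean_rr + x
            x = ar_coeff * x + innov_sd * rng.standard_normal()
    else:
        raise ValueError(f"unknown RR model: {model!r}")
    return RRSeries(rr_intervals=np.maximum(rr, 200.0))
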
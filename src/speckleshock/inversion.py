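"""Single-exposure contrast models, their numerical inversion to
decorrelation time, and velocity conversion.

Two forward models are provided, both assuming a negative-exponential
field autocorrelation:

* ``fercher_briers``:  K**2 = (tau/2T) * (1 - exp(-2T/tau))
* ``bandyopadhyay``:   K**2 = beta * [tau/T + tau**2/(2T**2) * (exp(-2T/tau) - 1)]

The second form accounts for triangular exposure weighting and the
speckle-averaging factor beta; its static limit is K -> sqrt(beta).
A ``literal_form`` flag equates K itself (not K**2) to the bracketed
expression times beta, for comparison with sources that print it that
way; it is not the default because it is inconsistent with the static
fully-developed limit K = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from speckleshock.contrast import spatial_contrast
from speckleshock.simulate import SpeckleStack

__all__ = [
    "ContrastModelSpec",
    "FlowEstimate",
    "contrast_fb",
    "contrast_bandyo",
    "invert_contrast",
    "velocity_from_tau",
    "estimate_beta",
]

_LOG_RATIO_BRACKET = (-6.0, 6.0)  # log10(tau_c / T) search range


@dataclass(frozen=True)
class ContrastModelSpec:
    model: str = "bandyopadhyay"  # or "fercher_briers"
    beta: float = 1.0
    literal_form: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("fercher_briers", "bandyopadhyay"):
            raise ValueError(f"unknown contrast model: {self.model!r}")
        if self.model == "bandyopadhyay" and not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")

    @property
    def static_limit(self) -> float:
        """Contrast in the no-flow limit T/tau_c -> 0."""
        if self.model == "fercher_briers":
            return 1.0
        if self.literal_form:
            return self.beta
        return float(np.sqrt(self.beta))

    def forward(self, T: float, tau_c) -> np.ndarray | float:
        if self.model == "fercher_briers":
            return contrast_fb(T, tau_c)
        return contrast_bandyo(T, tau_c, self.beta, literal_form=self.literal_form)


@dataclass(frozen=True)
class FlowEstimate:
    tau_c: float  # seconds
    velocity: float  # m/s
    model: ContrastModelSpec
    K_input: float
    T: float


def contrast_fb(T: float, tau_c) -> np.ndarray | float:
    """Single-exposure contrast, K = sqrt((tau/2T)(1 - exp(-2T/tau)))."""
    if T <= 0:
        raise ValueError("exposure time must be positive")
    tau = np.asarray(tau_c, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_c must be positive")
    x = T / tau  # 0 for tau = inf
    with np.errstate(invalid="ignore"):
        k2 = np.where(x > 0, -np.expm1(-2.0 * x) / np.where(x > 0, 2.0 * x, 1.0), 1.0)
    out = np.sqrt(k2)
    return float(out) if np.isscalar(tau_c) or out.ndim == 0 else out


def contrast_bandyo(T: float, tau_c, beta: float = 1.0, literal_form: bool = False):
    """Speckle-averaging-corrected contrast model.

    Default: K = sqrt(beta * [tau/T + tau**2/(2 T**2)(exp(-2T/tau) - 1)]);
    static limit sqrt(beta).  With ``literal_form=True``, K equals
    beta times the bracketed expression directly (static limit beta).
    """
    if T <= 0:
        raise ValueError("exposure time must be positive")
    if not 0 < beta <= 1:
        raise ValueError("beta must lie in (0, 1]")
    tau = np.asarray(tau_c, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau_c must be positive")
    x = T / tau  # 0 for tau = inf
    safe = np.where(x > 0, x, 1.0)
    bracket = np.where(x > 0, (np.expm1(-2.0 * safe) + 2.0 * safe) / (2.0 * safe**2), 1.0)
    out = beta * bracket if literal_form else np.sqrt(beta * bracket)
    return float(out) if np.isscalar(tau_c) or np.ndim(out) == 0 else out


def velocity_from_tau(tau_c: float, wavelength: float = 805e-9) -> float:
    """Scatterer velocity v = lambda / (2 pi tau_c), in m/s."""
    if tau_c <= 0 or wavelength <= 0:
        raise ValueError("tau_c and wavelength must be positive")
    return wavelength / (2.0 * np.pi * tau_c)


class NoSolutionError(ValueError):
    """Raised when a contrast value has no decorrelation-time solution."""


def invert_contrast(
    K: float,
    T: float,
    spec: ContrastModelSpec | None = None,
    wavelength: float = 805e-9,
    tol: float = 1e-12,
) -> FlowEstimate:
    """Invert a contrast value to decorrelation time and velocity.

    A bracketed root-find on log10(tau_c/T) over [-6, 6]; uniqueness is
    guaranteed by the strict monotonicity of the forward models in
    tau_c.  Raises :class:`NoSolutionError` when K is at or above the
    static limit, or below the contrast achievable in the bracket.
    """
    if spec is None:
        spec = ContrastModelSpec()
    if K <= 0:
        raise ValueError("K must be positive")
    if T <= 0:
        raise ValueError("exposure time must be positive")
    if K >= spec.static_limit:
        raise NoSolutionError(
            f"K = {K} is at/above the static limit {spec.static_limit:.6g}; "
            "no finite decorrelation time reproduces it"
        )

    lo, hi = _LOG_RATIO_BRACKET

    def residual(log_ratio: float) -> float:
        return spec.forward(T, T * 10.0**log_ratio) - K

    if residual(lo) > 0:
        raise NoSolutionError(
            f"K = {K} below the model contrast at tau_c/T = 1e{lo:.0f}; "
            "flow too fast to invert in the supported range"
        )
    if residual(hi) < 0:
        raise NoSolutionError(
            f"K = {K} too close to the static limit to invert within "
            f"tau_c/T <= 1e{hi:.0f}"
        )
    log_tau = brentq(residual, lo, hi, xtol=tol, rtol=8.9e-16)
    tau_c = T * 10.0**log_tau
    return FlowEstimate(
        tau_c=tau_c,
        velocity=velocity_from_tau(tau_c, wavelength),
        model=spec,
        K_input=K,
        T=T,
    )


def estimate_beta(static_stack: SpeckleStack, window: int | None = None) -> float:
    """Calibrate beta from a stack the user asserts is static.

    beta = mean over frames of K**2 with K the contrast over all valid
    pixels; for a static fully developed pattern this estimates the
    speckle-averaging factor.  By default the contrast is global
    (whole-frame), which avoids the small-window downward bias of the
    ratio estimator; pass ``window`` to use the mean windowed K**2
    instead (bias-corrected by n/(n-1)).
    """
    k2_per_frame = []
    n_valid = 0
    for i in range(static_stack.n_frames):
        frame = static_stack.frames[i]
        if window is None:
            mean = float(frame.mean())
            if mean == 0:
                k2_per_frame.append(0.0)
            else:
                k2_per_frame.append(float(frame.var()) / mean**2)
            n_valid += frame.size
        else:
            cmap = spatial_contrast(frame, window, frame_index=i)
            vals = cmap.K[cmap.valid_mask]
            n = window * window
            k2_per_frame.append(float(np.mean(vals * vals)) * n / (n - 1))
            n_valid += vals.size
    if n_valid < 1000:
        warnings.warn(
            f"only {n_valid} valid pixels: low-confidence beta estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    if not k2_per_frame:
        return 0.0
    return float(np.mean(k2_per_frame))
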
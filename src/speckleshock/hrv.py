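"""Heart-rate-variability metrics from RR-interval series.

Conventions (documented because they differ between sources):
SDRR uses the sample standard deviation (ddof=1).  The Poincare axes
use second moments about zero/mean such that the identity
``sd1 = rmssd / sqrt(2)`` holds exactly.  Spectral bands follow the
standard short-term HRV edges: VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz,
computed on a 4 Hz linearly interpolated tachogram with a Welch
periodogram.  SampEn uses m=2, r = 0.2 * SD, Chebyshev distance,
self-matches excluded.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import signal

from speckleshock.simulate import RRSeries

__all__ = [
    "BANDS",
    "time_domain",
    "poincare",
    "band_power",
    "sampen",
    "higuchi_fd",
    "hrv_summary",
]

BANDS: dict[str, tuple[float, float]] = {
    "VLF": (0.0033, 0.04),
    "LF": (0.04, 0.15),
}

_TACHO_FS = 4.0  # Hz, tachogram resampling rate


def _rr(rr) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.rr_intervals
    arr = np.asarray(rr, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least two RR intervals")
    return arr


def time_domain(rr) -> dict[str, float]:
    """SDRR (sample SD), RMSSD, and pNN50 (% successive diffs > 50 ms)."""
    x = _rr(rr)
    d = np.diff(x)
    return {
        "sdrr": float(np.std(x, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d * d))),
        "pnn50": float(100.0 * np.mean(np.abs(d) > 50.0)),
    }


def poincare(rr) -> dict[str, float]:
    """Poincare short- and long-axis dispersions SD1 and SD2.

    SD1 is the RMS of successive differences scaled by 1/sqrt(2) (so
    sd1 = rmssd/sqrt(2) identically); SD2 is the SD of successive sums
    about their mean, scaled by 1/sqrt(2).
    """
    x = _rr(rr)
    d = np.diff(x)
    s = x[1:] + x[:-1]
    sd1 = float(np.sqrt(np.mean(d * d) / 2.0))
    sd2 = float(np.std(s, ddof=0) / np.sqrt(2.0))
    return {"sd1": sd1, "sd2": sd2}


def _tachogram(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Evenly resampled RR tachogram at 4 Hz via linear interpolation."""
    t = np.cumsum(x) / 1000.0  # seconds, time of each beat
    t = t - t[0]
    duration = t[-1]
    grid = np.arange(0.0, duration, 1.0 / _TACHO_FS)
    return np.interp(grid, t, x), duration


def band_power(rr, band: str) -> float:
    """Spectral power (ms^2) of the RR tachogram in a named band.

    The series is resampled to 4 Hz, mean-removed, and estimated with a
    Welch periodogram; the band is integrated by the trapezoid rule.
    Recordings shorter than two cycles of the band's lower edge raise.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
    f_lo, f_hi = BANDS[band]
    x = _rr(rr)
    tach, duration = _tachogram(x)
    if duration < 1.0 / f_hi:
        raise ValueError(
            f"recording of {duration:.1f} s shorter than one cycle of the "
            f"fastest {band} frequency ({1.0 / f_hi:.0f} s)"
        )
    if duration < 2.0 / f_lo:
        warnings.warn(
            f"{band} power from a {duration:.0f}-s record covers fewer than "
            "two cycles of the band; low confidence",
            RuntimeWarning,
            stacklevel=2,
        )
    tach = tach - tach.mean()
    nperseg = min(tach.size, 1024)
    freqs, psd = signal.welch(tach, fs=_TACHO_FS, nperseg=nperseg, detrend="constant")
    sel = (freqs >= f_lo) & (freqs <= f_hi)
    if sel.sum() < 2:
        # too few bins inside the band: integrate the nearest bin mass
        return float(np.sum(psd[sel]) * (freqs[1] - freqs[0]))
    return float(np.trapezoid(psd[sel], freqs[sel]))


def sampen(rr, m: int = 2, r_frac: float = 0.2) -> float | None:
    """Sample entropy SampEn(m, r = r_frac * SD).

    Chebyshev distance, self-matches excluded, counting ordered pairs
    of templates of length m (B) and m+1 (A); returns -ln(A/B), or
    None when either count is zero (undefined, flagged rather than
    infinite).
    """
    x = _rr(rr)
    n = x.size
    if n < m + 2:
        raise ValueError("series too short for the requested embedding")
    sd = float(np.std(x, ddof=0))
    r = r_frac * sd
    if sd == 0:
        return 0.0  # constant series: all templates match at both lengths

    def _count(mm: int) -> int:
        n_t = n - m  # same template count at both lengths (standard convention)
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_t]
        total = 0
        for i in range(n_t - 1):
            dist = np.max(np.abs(templ[i + 1 :] - templ[i]), axis=1)
            total += int(np.sum(dist <= r))
        return total

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return None
    return float(-math.log(a / b))


def higuchi_fd(rr, k_max: int = 10) -> float:
    """Higuchi fractal dimension of the RR series.

    Computes the mean normalized curve length L(k) for k = 1..k_max and
    returns minus the slope of the least-squares fit of ln L(k) against
    ln k.  Roughly 1 for smooth curves and 2 for white noise.
    """
    x = _rr(rr)
    if k_max < 2:
        raise ValueError("k_max must be >= 2 (need at least two scales)")
    n = x.size
    if n <= k_max:
        raise ValueError("series shorter than k_max")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m0 in range(k):
            idx = np.arange(m0, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(dist * norm / k)
        lk[k - 1] = np.mean(lengths)
    ks = np.arange(1, k_max + 1)
    valid = lk > 0
    if valid.sum() < 2:
        return 1.0  # flat series: zero curve length at every scale
    slope = np.polyfit(np.log(ks[valid]), np.log(lk[valid]), 1)[0]
    return float(-slope)


def hrv_summary(rr, k_max: int = 10) -> dict[str, float | None]:
    """All supported HRV metrics for one RR series."""
    out: dict[str, float | None] = {}
    out.update(time_domain(rr))
    out.update(poincare(rr))
    for band in BANDS:
        try:
            out[f"{band.lower()}_power"] = band_power(rr, band)
        except ValueError:
            out[f"{band.lower()}_power"] = None
    out["sampen"] = sampen(rr)
    try:
        out["higuchi_fd"] = higuchi_fd(rr, k_max=k_max)
    except ValueError:
        out["higuchi_fd"] = None
    return out
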
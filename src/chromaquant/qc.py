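"""Per-analyte quality-control criteria.

Three criteria are computed per analyte window: the residual retention
time (absolute difference between the spline-apex observed t_r and the
expected t_r), the signal-to-noise ratio against a lowest-mean-window
background/noise estimate, and the Gaussian Peak Quality (analytic area
of a fitted Gaussian divided by the background-subtracted integrated
area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.optimize import curve_fit, minimize_scalar

from .baseline_noise import NoiseEstimate
from .chromatogram_io import Chromatogram, PeakDefinition
from .peak_detection import SQRT_TWO_PI, gaussian

__all__ = [
    "QcMetrics",
    "QcError",
    "observed_retention_time",
    "residual_retention_time",
    "signal_to_noise",
    "gaussian_peak_quality",
]


class QcError(ValueError):
    """Raised for windows unsuitable for a QC computation."""


@dataclass(frozen=True)
class QcMetrics:
    rt_residual: float
    sn: float
    gpq: float


def _window_arrays(
    chrom: Chromatogram, peak: PeakDefinition
) -> tuple[np.ndarray, np.ndarray]:
    mask = (chrom.time >= peak.start) & (chrom.time <= peak.end)
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    if t.size == 0:
        raise QcError(f"analyte {peak.name!r}: window contains no data points")
    return t, y


def observed_retention_time(chrom: Chromatogram, peak: PeakDefinition) -> float:
    """Continuous apex position of an interpolating spline in the window.

    The spline is evaluated on a 10x-oversampled grid and the best grid
    point is refined by bounded scalar maximisation, giving sub-sample
    apex resolution.  Deterministic.
    """
    t, y = _window_arrays(chrom, peak)
    if t.size < 4:
        raise QcError(
            f"analyte {peak.name!r}: need >= 4 points for the spline apex, got {t.size}"
        )
    spline = InterpolatedUnivariateSpline(t, y, k=3)
    dense = np.linspace(t[0], t[-1], 10 * t.size)
    values = spline(dense)
    i = int(np.argmax(values))
    lo = dense[max(i - 1, 0)]
    hi = dense[min(i + 1, dense.size - 1)]
    if lo == hi:
        return float(dense[i])
    res = minimize_scalar(
        lambda x: -float(spline(x)), bounds=(lo, hi), method="bounded"
    )
    return float(res.x) if res.success else float(dense[i])


def residual_retention_time(chrom: Chromatogram, peak: PeakDefinition) -> float:
    """Absolute difference between observed (spline apex) and expected t_r."""
    return abs(observed_retention_time(chrom, peak) - peak.tr_expected)


def signal_to_noise(
    chrom: Chromatogram, peak: PeakDefinition, noise: NoiseEstimate
) -> float:
    """(window maximum - background) / noise."""
    if noise.noise <= 0:
        raise QcError(
            "noise estimate is zero; use a larger noise window or a noisier region"
        )
    _, y = _window_arrays(chrom, peak)
    return (float(y.max()) - noise.background) / noise.noise


def gaussian_peak_quality(
    chrom: Chromatogram, peak: PeakDefinition, noise: NoiseEstimate
) -> float:
    """Ratio of fitted-Gaussian area to background-subtracted integrated area.

    The background is subtracted from every window point, a single
    Gaussian is fitted to the subtracted points, and the analytic area
    of the fit (amplitude * sigma * sqrt(2*pi)) is divided by the
    integrated area (sampling interval times the summed subtracted
    intensities).  Values near 1 indicate a clean Gaussian peak; tailing,
    fronting and overlap push the ratio away from 1.  Returns ``nan``
    when the fit fails.
    """
    t, y = _window_arrays(chrom, peak)
    if t.size < 4:
        raise QcError(
            f"analyte {peak.name!r}: need >= 4 points for a Gaussian fit, got {t.size}"
        )
    y_sub = y - noise.background
    t_m = float(np.median(np.diff(t)))
    integrated = t_m * float(y_sub.sum())
    if integrated == 0:
        raise QcError(f"analyte {peak.name!r}: zero integrated area")
    i_apex = int(np.argmax(y_sub))
    width = float(t[-1] - t[0])
    p0 = (max(float(y_sub[i_apex]), t_m), float(t[i_apex]), width / 4.0)
    try:
        popt, _ = curve_fit(
            gaussian,
            t,
            y_sub,
            p0=p0,
            bounds=((0.0, t[0] - width, t_m / 10.0), (np.inf, t[-1] + width, 2 * width)),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return math.nan
    amplitude, _, sigma = map(float, popt)
    return amplitude * sigma * SQRT_TWO_PI / integrated
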
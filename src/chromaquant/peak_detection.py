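"""First-derivative Gaussian peak detection.

Peaks are found by fitting a smoothing spline to the signal in a
region of interest, bracketing candidate apexes between successive
local maxima and minima of the spline's first derivative, fitting a
Gaussian to the bracket holding the globally highest residual point,
subtracting the Gaussian, and repeating until the highest residual
intensity drops below a relative cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.optimize import curve_fit

from .baseline_noise import NoiseEstimate
from .chromatogram_io import Chromatogram, PeakDefinition

__all__ = [
    "FWHM_FACTOR",
    "DetectedPeak",
    "DetectionSettings",
    "DetectionError",
    "derivative_brackets",
    "detect_peaks",
    "peaks_to_definitions",
    "suggest_calibrants",
]

log = logging.getLogger(__name__)

#: full width at half maximum of a unit-sigma Gaussian
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

SQRT_TWO_PI = math.sqrt(2.0 * math.pi)


class DetectionError(ValueError):
    """Raised for invalid detection input."""


@dataclass(frozen=True)
class DetectedPeak:
    """One fitted Gaussian component of the signal."""

    center: float
    sigma: float
    amplitude: float
    bracket: tuple[float, float]
    iteration: int

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma

    @property
    def area(self) -> float:
        """Analytic Gaussian area, amplitude * sigma * sqrt(2*pi)."""
        return self.amplitude * self.sigma * SQRT_TWO_PI


@dataclass(frozen=True)
class DetectionSettings:
    """Parameters controlling peak detection.

    ``cutoff_fraction`` is relative to the background-subtracted initial
    maximum; ``spline_smoothing`` of ``None`` selects the heuristic
    ``n * noise**2``.
    """

    region: tuple[float, float]
    cutoff_fraction: float = 0.01
    max_iterations: int = 50
    spline_smoothing: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_fraction < 1.0:
            raise ValueError("cutoff_fraction must lie strictly between 0 and 1")
        if self.region[0] >= self.region[1]:
            raise ValueError("region start must precede region end")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.spline_smoothing is not None and self.spline_smoothing < 0:
            raise ValueError("spline_smoothing must be >= 0")


def gaussian(t: np.ndarray, amplitude: float, center: float, sigma: float) -> np.ndarray:
    """Gaussian peak shape without offset."""
    return amplitude * np.exp(-((t - center) ** 2) / (2.0 * sigma**2))


def _spline_brackets(
    t: np.ndarray, y: np.ndarray, smoothing: float
) -> list[tuple[float, float]]:
    spline = UnivariateSpline(t, y, k=3, s=smoothing)
    deriv = spline.derivative()(t)
    # interior local extrema of f' on the sampling grid
    rising = np.diff(deriv) > 0
    maxima = [i for i in range(1, t.size - 1) if rising[i - 1] and not rising[i]]
    minima = [i for i in range(1, t.size - 1) if not rising[i - 1] and rising[i]]
    # derivative swings below this are numerical wiggle, not peaks
    t_m = float(np.median(np.diff(t)))
    significance = max(1e-8 * float(y.max() - y.min()) / t_m, 1e-12)
    brackets: list[tuple[float, float]] = []
    mi = 0
    for i_max in maxima:
        while mi < len(minima) and minima[mi] <= i_max:
            mi += 1
        if mi == len(minima):
            break
        if deriv[i_max] - deriv[minima[mi]] > significance:
            brackets.append((float(t[i_max]), float(t[minima[mi]])))
    return brackets


def _resolve_smoothing(
    settings: DetectionSettings, n: int, noise: NoiseEstimate | None
) -> float:
    if settings.spline_smoothing is not None:
        return settings.spline_smoothing
    if noise is None:
        return 0.0
    return n * noise.noise**2


def derivative_brackets(
    chrom: Chromatogram,
    settings: DetectionSettings,
    noise: NoiseEstimate | None = None,
) -> list[tuple[float, float]]:
    """Bracket candidate apexes between extrema of the spline derivative.

    Returns intervals ``[t_max, t_min]`` where ``t_max`` is a local
    maximum of the first derivative of a smoothing spline through the
    region and ``t_min`` the next local minimum after it; each interval
    brackets one candidate apex.  A flat signal yields no intervals.
    """
    sub = chrom.slice(*settings.region)
    if len(sub) < 10:
        raise DetectionError("need at least 10 data points in the detection region")
    smoothing = _resolve_smoothing(settings, len(sub), noise)
    return _spline_brackets(sub.time, sub.intensity, smoothing)


def _fit_bracket(
    t: np.ndarray,
    y: np.ndarray,
    background: float,
    t_m: float,
) -> tuple[float, float, float] | None:
    """Fit background + Gaussian over one bracket; None on failure."""
    if t.size < 4:
        return None
    width = float(t[-1] - t[0])
    i_apex = int(np.argmax(y))
    amp0 = max(float(y[i_apex]) - background, t_m)
    p0 = (amp0, float(t[i_apex]), max(width / 4.0, t_m * 1.01))
    lower = (0.0, float(t[0]) - width, t_m)
    upper = (np.inf, float(t[-1]) + width, max(width, t_m * 1.02))
    try:
        popt, _ = curve_fit(
            lambda tt, a, mu, sig: background + gaussian(tt, a, mu, sig),
            t,
            y,
            p0=p0,
            bounds=(lower, upper),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None
    amplitude, center, sigma = map(float, popt)
    if amplitude <= 0 or sigma <= 0:
        return None
    return amplitude, center, sigma


def detect_peaks(
    chrom: Chromatogram,
    settings: DetectionSettings,
    noise: NoiseEstimate,
) -> list[DetectedPeak]:
    """Iteratively fit and subtract Gaussians until the cutoff is reached.

    Each iteration refits the smoothing spline on the current residual,
    finds the derivative bracket containing the globally highest
    residual point, fits a Gaussian (on top of the constant background
    from ``noise``) to that bracket and subtracts it from the residual
    over the whole region.  The loop stops once the background-
    subtracted residual maximum falls below ``cutoff_fraction`` of the
    background-subtracted initial maximum.  Peaks are returned sorted by
    center; residuals may go negative and are kept so that area is
    conserved.
    """
    sub = chrom.slice(*settings.region)
    if len(sub) < 10:
        raise DetectionError("need at least 10 data points in the detection region")
    t = sub.time
    residual = sub.intensity.copy()
    t_m = sub.sampling_interval
    background = noise.background
    smoothing = _resolve_smoothing(settings, len(sub), noise)

    initial_max = float(residual.max()) - background
    if initial_max <= 0:
        return []
    threshold = settings.cutoff_fraction * initial_max

    masked = np.zeros(t.size, dtype=bool)
    peaks: list[DetectedPeak] = []
    for iteration in range(1, settings.max_iterations + 1):
        work = np.where(masked, -np.inf, residual)
        apex = int(np.argmax(work))  # ties: earliest point wins
        if work[apex] - background < threshold:
            break
        brackets = _spline_brackets(t, residual, smoothing)
        chosen = None
        chosen_idx = None
        for i, (lo, hi) in enumerate(brackets):
            if lo <= t[apex] <= hi:
                chosen = (lo, hi)
                chosen_idx = i
                break
        if chosen is None:
            masked[apex] = True
            continue
        # the derivative extrema sit near the inflection points (+-sigma);
        # widen the fitted stretch by half a bracket width per side, but
        # never into a neighbouring bracket
        width = chosen[1] - chosen[0]
        fit_lo = chosen[0] - 0.5 * width
        fit_hi = chosen[1] + 0.5 * width
        if chosen_idx > 0:
            fit_lo = max(fit_lo, brackets[chosen_idx - 1][1])
        if chosen_idx + 1 < len(brackets):
            fit_hi = min(fit_hi, brackets[chosen_idx + 1][0])
        in_bracket = (t >= fit_lo) & (t <= fit_hi)
        fit = _fit_bracket(t[in_bracket], residual[in_bracket], background, t_m)
        if fit is None:
            log.debug("Gaussian fit failed in bracket %s; masking apex", chosen)
            masked[apex] = True
            continue
        amplitude, center, sigma = fit
        peaks.append(
            DetectedPeak(
                center=center,
                sigma=sigma,
                amplitude=amplitude,
                bracket=chosen,
                iteration=iteration,
            )
        )
        residual -= gaussian(t, amplitude, center, sigma)
    else:
        log.warning(
            "peak detection truncated at max_iterations=%d", settings.max_iterations
        )
    return sorted(peaks, key=lambda p: p.center)


def peaks_to_definitions(peaks: list[DetectedPeak]) -> list[PeakDefinition]:
    """Convert detected peaks to a quantitation peak list.

    Peaks are named ``peak1..peakN`` in retention-time order; the window
    half-width is FWHM/2 of the fitted Gaussian.
    """
    if not peaks:
        raise DetectionError("no peaks to convert")
    ordered = sorted(peaks, key=lambda p: p.center)
    return [
        PeakDefinition(name=f"peak{i}", tr_expected=p.center, window=p.fwhm / 2.0)
        for i, p in enumerate(ordered, start=1)
    ]


def suggest_calibrants(peaks: list[DetectedPeak], k: int = 4) -> list[PeakDefinition]:
    """Pick ``k`` intense peaks spaced as evenly as possible in t_r.

    The detected retention-time span is split into ``k`` equal
    sub-spans and the highest-amplitude peak of each sub-span is chosen;
    empty sub-spans fall back to the next-highest-amplitude unused peak
    overall.  With fewer than ``k`` peaks, all peaks are returned with a
    warning.
    """
    if not peaks:
        raise DetectionError("no peaks to choose calibrants from")
    ordered = sorted(peaks, key=lambda p: p.center)
    if len(ordered) < k:
        log.warning("only %d peaks available for %d calibrants", len(ordered), k)
        chosen = list(ordered)
    else:
        lo, hi = ordered[0].center, ordered[-1].center
        span = hi - lo
        chosen = []
        used: set[int] = set()
        for j in range(k):
            a = lo + span * j / k
            b = lo + span * (j + 1) / k
            in_span = [
                (i, p)
                for i, p in enumerate(ordered)
                if i not in used and (a <= p.center < b or (j == k - 1 and p.center == b))
            ]
            if in_span:
                i_best, _ = max(in_span, key=lambda ip: ip[1].amplitude)
                used.add(i_best)
            else:
                remaining = [(i, p) for i, p in enumerate(ordered) if i not in used]
                i_best, _ = max(remaining, key=lambda ip: ip[1].amplitude)
                used.add(i_best)
        chosen = [ordered[i] for i in sorted(used)]
    return [
        PeakDefinition(name=f"cal{i}", tr_expected=p.center, window=p.fwhm / 2.0)
        for i, p in enumerate(chosen, start=1)
    ]
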
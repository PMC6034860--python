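"""Background/noise estimation and low-order baseline correction.

The background and noise of a region are taken from the contiguous run
of ``window_points`` data points with the lowest mean intensity: the
mean of that run is the background, its (population) standard deviation
the noise.  The baseline is a low-order polynomial fitted through
block-minimum support points and subtracted pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromatogram_io import Chromatogram

__all__ = [
    "NoiseEstimate",
    "BaselineError",
    "estimate_background_noise",
    "fit_baseline",
    "subtract_baseline",
]


class BaselineError(ValueError):
    """Raised when a region holds too few points for the estimate."""


@dataclass(frozen=True)
class NoiseEstimate:
    """Lowest-mean-window background and noise for a region."""

    background: float
    noise: float
    window_start: float
    window_points: int

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.window_points < 2:
            raise ValueError("window_points must be >= 2")


def _region_mask(chrom: Chromatogram, region: tuple[float, float] | None) -> np.ndarray:
    if region is None:
        return np.ones(len(chrom), dtype=bool)
    start, end = region
    return (chrom.time >= start) & (chrom.time <= end)


def estimate_background_noise(
    chrom: Chromatogram,
    region: tuple[float, float] | None = None,
    window_points: int = 100,
) -> NoiseEstimate:
    """Find the lowest-mean run of ``window_points`` consecutive points.

    Scans every contiguous window of ``window_points`` data points
    inside ``region`` (whole chromatogram when ``None``) and returns the
    mean (background) and standard deviation (noise) of the window with
    the minimal mean.  Ties resolve to the earliest window.
    """
    if window_points < 2:
        raise BaselineError("window_points must be >= 2")
    mask = _region_mask(chrom, region)
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    if y.size < window_points:
        raise BaselineError(
            f"region holds {y.size} points, fewer than window_points={window_points}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(y, window_points)
    means = windows.mean(axis=1)
    idx = int(np.argmin(means))  # argmin returns the first minimum
    return NoiseEstimate(
        background=float(means[idx]),
        noise=float(windows[idx].std()),
        window_start=float(t[idx]),
        window_points=window_points,
    )


def fit_baseline(
    chrom: Chromatogram,
    region: tuple[float, float] | None = None,
    order: int = 1,
    window_points: int = 100,
) -> np.ndarray:
    """Fit a polynomial baseline through block-minimum support points.

    The region is partitioned into consecutive blocks of
    ``window_points`` points; the minimum-intensity point of each block
    is a support point, and a least-squares polynomial of the given
    order is fitted through the support points.

    Returns
    -------
    numpy.ndarray
        Polynomial coefficients, highest degree first (``numpy.polyval``
        convention).
    """
    if order not in (0, 1, 2):
        raise BaselineError(f"baseline order must be 0, 1 or 2, got {order}")
    mask = _region_mask(chrom, region)
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    if y.size < window_points:
        raise BaselineError(
            f"region holds {y.size} points, fewer than window_points={window_points}"
        )
    support_t, support_y = [], []
    for start in range(0, y.size, window_points):
        block_y = y[start : start + window_points]
        block_t = t[start : start + window_points]
        j = int(np.argmin(block_y))
        support_t.append(block_t[j])
        support_y.append(block_y[j])
    if len(support_t) < order + 1:
        raise BaselineError(
            f"{len(support_t)} baseline support points cannot determine an "
            f"order-{order} polynomial"
        )
    return np.polyfit(np.asarray(support_t), np.asarray(support_y), order)


def subtract_baseline(chrom: Chromatogram, coefficients: np.ndarray) -> Chromatogram:
    """Subtract a fitted polynomial baseline from the signal pointwise."""
    corrected = chrom.intensity - np.polyval(np.asarray(coefficients), chrom.time)
    return chrom.with_values(intensity=corrected)
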
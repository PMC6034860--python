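"""Retention-time calibration against a calibrant peak list.

Observed calibrant retention times (highest data point inside each
calibrant window) are gated on signal-to-noise; a degree-2 polynomial
mapping observed to expected retention time is fitted through the
retained calibrants and applied to the whole time axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baseline_noise import BaselineError, estimate_background_noise
from .chromatogram_io import Chromatogram, PeakDefinition
from .qc import QcError, signal_to_noise

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "find_observed_tr",
    "calibrate",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when a chromatogram cannot be calibrated."""

    def __init__(self, message: str, rejected: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.rejected = rejected or []


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted degree-2 mapping and the calibrants that produced it."""

    coefficients: np.ndarray  # highest degree first (numpy.polyval convention)
    used_calibrants: list[tuple[str, float, float]]  # (name, observed, expected)
    rejected_calibrants: list[tuple[str, str]]  # (name, reason)

    def apply(self, time: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(time, dtype=float))


def find_observed_tr(chrom: Chromatogram, peak: PeakDefinition) -> float:
    """Time of the highest-intensity data point in the calibrant window.

    Ties resolve to the earliest data point.
    """
    mask = (chrom.time >= peak.start) & (chrom.time <= peak.end)
    if not mask.any():
        raise CalibrationError(
            f"calibrant {peak.name!r}: window [{peak.start:.4g}, {peak.end:.4g}] "
            "contains no data points"
        )
    idx = int(np.argmax(chrom.intensity[mask]))
    return float(chrom.time[mask][idx])


def calibrate(
    chrom: Chromatogram,
    calibrants: Sequence[PeakDefinition],
    min_sn: float = 9.0,
    min_calibrants: int = 4,
    background_window: float = 1.0,
    noise_points: int = 100,
) -> tuple[Chromatogram, CalibrationResult]:
    """Calibrate the time axis of a chromatogram against calibrant peaks.

    Per calibrant, the observed retention time is the highest data
    point inside its window and the signal-to-noise ratio is computed
    against a lowest-mean-window background/noise estimate taken within
    ``background_window`` minutes around the calibrant.  Calibrants
    with S/N below ``min_sn`` are rejected.  If at least
    ``min_calibrants`` remain, a least-squares degree-2 polynomial is
    fitted through the (observed, expected) pairs and applied to the
    time axis; otherwise a :class:`CalibrationError` lists the
    rejections.  A mapping that does not keep the time axis strictly
    increasing also fails.
    """
    if min_calibrants < 3:
        raise ValueError("min_calibrants must be >= 3 for a degree-2 fit")
    used: list[tuple[str, float, float]] = []
    rejected: list[tuple[str, str]] = []
    for cal in calibrants:
        try:
            observed = find_observed_tr(chrom, cal)
            noise = estimate_background_noise(
                chrom,
                region=(cal.tr_expected - background_window, cal.tr_expected + background_window),
                window_points=noise_points,
            )
            sn = signal_to_noise(chrom, cal, noise)
        except (CalibrationError, BaselineError, QcError) as exc:
            rejected.append((cal.name, str(exc)))
            continue
        if sn < min_sn:
            rejected.append((cal.name, f"S/N {sn:.3g} below threshold {min_sn:.3g}"))
            continue
        used.append((cal.name, observed, cal.tr_expected))
    if len(used) < min_calibrants:
        raise CalibrationError(
            f"only {len(used)} of {len(calibrants)} calibrants passed "
            f"(minimum {min_calibrants}); rejected: "
            + "; ".join(f"{n}: {r}" for n, r in rejected),
            rejected=rejected,
        )
    obs = np.array([u[1] for u in used])
    exp = np.array([u[2] for u in used])
    coefficients = np.polyfit(obs, exp, 2)
    new_time = np.polyval(coefficients, chrom.time)
    if not np.all(np.diff(new_time) > 0):
        raise CalibrationError(
            "calibration polynomial is non-monotone over the data range",
            rejected=rejected,
        )
    result = CalibrationResult(
        coefficients=coefficients,
        used_calibrants=used,
        rejected_calibrants=rejected,
    )
    return chrom.with_values(time=new_time), result
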
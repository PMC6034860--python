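"""Integration-based peak quantitation.

The absolute area of an analyte window is the sum over its data points
of the sampling interval times the (background-subtracted) intensity;
relative areas normalise over all quantified analytes of a
chromatogram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .baseline_noise import BaselineError, estimate_background_noise
from .chromatogram_io import Chromatogram, PeakDefinition
from .config import ProcessingConfig
from .qc import QcError, gaussian_peak_quality, residual_retention_time, signal_to_noise

__all__ = [
    "AnalyteResult",
    "QuantitationError",
    "integrate_peak",
    "quantify_chromatogram",
]

log = logging.getLogger(__name__)


class QuantitationError(ValueError):
    """Raised when an analyte window cannot be integrated."""


@dataclass(frozen=True)
class AnalyteResult:
    """Per-analyte quantitation record for one chromatogram."""

    name: str
    area_abs: float
    area_rel: float
    background: float
    noise: float
    sn: float
    rt_residual: float
    gpq: float
    missing: bool = False

    @classmethod
    def missing_result(cls, name: str) -> "AnalyteResult":
        nan = math.nan
        return cls(
            name=name,
            area_abs=nan,
            area_rel=nan,
            background=nan,
            noise=nan,
            sn=nan,
            rt_residual=nan,
            gpq=nan,
            missing=True,
        )


def integrate_peak(
    chrom: Chromatogram, peak: PeakDefinition, background: float = 0.0
) -> float:
    """Integrate an analyte window: sum of t_m * (I_i - background).

    The window is the closed interval [t_r - dt, t_r + dt]; t_m is the
    median successive time difference within the window.  Negative point
    contributions are retained.
    """
    mask = (chrom.time >= peak.start) & (chrom.time <= peak.end)
    t = chrom.time[mask]
    y = chrom.intensity[mask]
    if t.size < 2:
        raise QuantitationError(
            f"analyte {peak.name!r}: window [{peak.start:.4g}, {peak.end:.4g}] "
            f"holds {t.size} data points (need >= 2)"
        )
    t_m = float(np.median(np.diff(t)))
    return t_m * float((y - background).sum())


def quantify_chromatogram(
    chrom: Chromatogram,
    analytes: Sequence[PeakDefinition],
    config: ProcessingConfig | None = None,
) -> list[AnalyteResult]:
    """Quantify every analyte window of a (calibrated) chromatogram.

    Per analyte, background and noise come from the lowest-mean window
    of ``config.baseline_points`` points within
    ``config.background_window`` minutes around the analyte; the
    absolute area is the background-subtracted integral (subtraction
    can be disabled via ``config.subtract_background``); S/N, residual
    retention time and Gaussian Peak Quality are appended.  Analytes
    whose window falls outside the data are flagged missing and
    excluded from the relative-area denominator.
    """
    config = config or ProcessingConfig()
    if not analytes:
        raise QuantitationError("empty analyte list")
    partial: list[AnalyteResult] = []
    for peak in analytes:
        try:
            noise = estimate_background_noise(
                chrom,
                region=(
                    peak.tr_expected - config.background_window,
                    peak.tr_expected + config.background_window,
                ),
                window_points=config.baseline_points,
            )
            background = noise.background if config.subtract_background else 0.0
            area = integrate_peak(chrom, peak, background)
            sn = signal_to_noise(chrom, peak, noise)
            rt = residual_retention_time(chrom, peak)
            gpq = gaussian_peak_quality(chrom, peak, noise)
        except (BaselineError, QuantitationError, QcError) as exc:
            log.warning("analyte %s flagged missing: %s", peak.name, exc)
            partial.append(AnalyteResult.missing_result(peak.name))
            continue
        partial.append(
            AnalyteResult(
                name=peak.name,
                area_abs=area,
                area_rel=math.nan,  # filled below
                background=noise.background,
                noise=noise.noise,
                sn=sn,
                rt_residual=rt,
                gpq=gpq,
            )
        )
    total = sum(r.area_abs for r in partial if not r.missing)
    if not any(not r.missing for r in partial):
        raise QuantitationError("no analyte could be quantified")
    if total <= 0:
        raise QuantitationError(
            f"non-positive total area {total:.4g}; cannot compute relative areas"
        )
    results = []
    for r in partial:
        if r.missing:
            results.append(r)
        else:
            results.append(
                AnalyteResult(
                    name=r.name,
                    area_abs=r.area_abs,
                    area_rel=r.area_abs / total,
                    background=r.background,
                    noise=r.noise,
                    sn=r.sn,
                    rt_residual=r.rt_residual,
                    gpq=r.gpq,
                )
            )
    return results
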
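"""Synthetic chromatogram generator with known ground truth.

Produces multi-peak chromatograms (Gaussian or exponentially modified
Gaussian shapes) with polynomial baseline drift, white noise and an
optional polynomial retention warp, plus replicate sets with controlled
area and retention jitter.  All randomness derives deterministically
from the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import exponnorm

from .chromatogram_io import Chromatogram, Dialect
from .peak_detection import SQRT_TWO_PI, gaussian

__all__ = [
    "PeakSpec",
    "SimSpec",
    "GroundTruthPeak",
    "simulate_chromatogram",
    "simulate_replicates",
]


@dataclass(frozen=True)
class PeakSpec:
    """Ground-truth peak: Gaussian, or EMG when ``tau > 0``."""

    center: float
    sigma: float
    amplitude: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    @property
    def area(self) -> float:
        """Analytic area; the EMG is normalised to the Gaussian area."""
        return self.amplitude * self.sigma * SQRT_TWO_PI


@dataclass(frozen=True)
class SimSpec:
    """Complete description of one simulated chromatogram."""

    peaks: tuple[PeakSpec, ...]
    region: tuple[float, float] = (0.0, 20.0)
    sampling_interval: float = 0.01
    baseline: tuple[float, ...] = (0.0,)  # polynomial, highest degree first
    noise_sigma: float = 0.0
    warp: tuple[float, ...] | None = None  # degree <= 2, highest degree first
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        object.__setattr__(self, "baseline", tuple(self.baseline))
        if self.warp is not None:
            warp = tuple(self.warp)
            if len(warp) > 3:
                raise ValueError("warp polynomial degree must be <= 2")
            object.__setattr__(self, "warp", warp)
        if self.region[0] >= self.region[1]:
            raise ValueError("region start must precede region end")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GroundTruthPeak:
    """True (post-warp) location and area of one simulated peak."""

    center: float
    sigma: float
    amplitude: float
    tau: float
    area: float


def _shape(t: np.ndarray, peak: PeakSpec, center: float) -> np.ndarray:
    if peak.tau == 0.0:
        return gaussian(t, peak.amplitude, center, peak.sigma)
    # EMG scaled to the same analytic area as the tau=0 Gaussian
    return peak.area * exponnorm.pdf(
        t, peak.tau / peak.sigma, loc=center, scale=peak.sigma
    )


def simulate_chromatogram(
    spec: SimSpec,
) -> tuple[Chromatogram, list[GroundTruthPeak]]:
    """Render a spec into a chromatogram plus its ground truth.

    The signal is the sum of the peak shapes (centers moved by the
    retention warp when one is given) plus the polynomial baseline plus
    white Gaussian noise drawn from ``numpy.random.default_rng(seed)``.
    """
    start, end = spec.region
    n = int(round((end - start) / spec.sampling_interval)) + 1
    t = start + spec.sampling_interval * np.arange(n)
    signal = np.polyval(np.asarray(spec.baseline, dtype=float), t)
    truth: list[GroundTruthPeak] = []
    for peak in spec.peaks:
        center = peak.center
        if spec.warp is not None:
            center = float(np.polyval(np.asarray(spec.warp, dtype=float), center))
        signal = signal + _shape(t, peak, center)
        truth.append(
            GroundTruthPeak(
                center=center,
                sigma=peak.sigma,
                amplitude=peak.amplitude,
                tau=peak.tau,
                area=peak.area,
            )
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=n)
    chrom = Chromatogram(
        sample_id=spec.sample_id,
        time=t,
        intensity=signal,
        source_path="",
        dialect=Dialect.PLAIN_TSV,
    )
    return chrom, truth


def simulate_replicates(
    spec: SimSpec,
    n: int,
    area_cv: float = 0.0,
    shift_sd: float = 0.0,
) -> list[tuple[Chromatogram, list[GroundTruthPeak]]]:
    """Simulate ``n`` replicate injections of the same sample.

    Per replicate, peak amplitudes are jittered lognormally with
    coefficient of variation ``area_cv`` and centers jittered normally
    with standard deviation ``shift_sd``.  Per-replicate seeds are
    spawned deterministically from ``spec.seed`` via
    ``numpy.random.SeedSequence`` so replicate ``i`` is stable
    regardless of how many replicates are requested.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    if area_cv < 0 or shift_sd < 0:
        raise ValueError("area_cv and shift_sd must be >= 0")
    children = np.random.SeedSequence(spec.seed).spawn(n)
    sigma_log = math.sqrt(math.log(1.0 + area_cv**2)) if area_cv > 0 else 0.0
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        peaks = []
        for peak in spec.peaks:
            amp = peak.amplitude
            if sigma_log > 0:
                # mean-preserving lognormal jitter
                amp *= rng.lognormal(-0.5 * sigma_log**2, sigma_log)
            center = peak.center
            if shift_sd > 0:
                center += rng.normal(0.0, shift_sd)
            peaks.append(replace(peak, amplitude=amp, center=center))
        rep_spec = replace(
            spec,
            peaks=tuple(peaks),
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=f"{spec.sample_id}_rep{i + 1}",
        )
        out.append(simulate_chromatogram(rep_spec))
    return out
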
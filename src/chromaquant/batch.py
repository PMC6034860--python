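"""Batch orchestration: calibrate and quantify a folder of chromatograms.

Per file: read, optionally calibrate, quantify, write a per-sample
result table; afterwards aggregate the mean, standard deviation and
coefficient of variation of the relative areas per analyte across the
successful samples.  Individual failures are recorded and never abort
the batch.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import CalibrationError, calibrate
from .chromatogram_io import (
    Chromatogram,
    ChromatogramError,
    PeakDefinition,
    read_chromatogram,
    write_chromatogram,
)
from .config import ProcessingConfig
from .quantitation import AnalyteResult, QuantitationError, quantify_chromatogram

__all__ = [
    "AnalyteSummary",
    "BatchSummary",
    "BatchError",
    "run_batch",
    "compute_fab_glycosylation",
    "fab_glycosylation_from_profiles",
    "G2S2_PEAKS",
    "G1F_TOTAL_PEAKS",
    "export_overlay",
]

log = logging.getLogger(__name__)

CHROMATOGRAM_EXTENSIONS = (".txt", ".arw", ".tsv")

RESULT_COLUMNS = (
    "name",
    "area_abs",
    "area_rel",
    "background",
    "noise",
    "sn",
    "rt_residual",
    "gpq",
)

_FMT = "{:.6g}"  # fixed 6-significant-digit output for reproducible diffs


class BatchError(RuntimeError):
    """Raised when no sample in a batch could be processed."""


@dataclass(frozen=True)
class AnalyteSummary:
    """Replicate statistics of one analyte's relative area."""

    name: str
    mean_area_rel: float
    sd_area_rel: float
    cv_percent: float  # nan when n < 2 or mean <= 0
    n: int


@dataclass(frozen=True)
class BatchSummary:
    analytes: list[AnalyteSummary]
    n_samples: int
    failed_samples: list[tuple[str, str]]
    per_sample: dict[str, list[AnalyteResult]] = field(default_factory=dict)


def _fmt(value: float) -> str:
    return "nan" if math.isnan(value) else _FMT.format(value)


def write_results_table(
    results: Sequence[AnalyteResult], path: str | os.PathLike
) -> None:
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        lines.append(
            "\t".join(
                [r.name]
                + [
                    _fmt(getattr(r, col))
                    for col in RESULT_COLUMNS[1:]
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def summarize(
    per_sample: Mapping[str, Sequence[AnalyteResult]],
    analytes: Sequence[PeakDefinition],
) -> list[AnalyteSummary]:
    """Aggregate mean/sd/CV of relative areas per analyte across samples."""
    out = []
    for peak in analytes:
        values = [
            r.area_rel
            for results in per_sample.values()
            for r in results
            if r.name == peak.name and not r.missing
        ]
        n = len(values)
        if n == 0:
            out.append(AnalyteSummary(peak.name, math.nan, math.nan, math.nan, 0))
            continue
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if n >= 2 else math.nan
        cv = 100.0 * sd / mean if n >= 2 and mean > 0 else math.nan
        out.append(AnalyteSummary(peak.name, mean, sd, cv, n))
    return out


def run_batch(
    input_dir: str | os.PathLike,
    analytes: Sequence[PeakDefinition],
    calibrants: Sequence[PeakDefinition] | None = None,
    config: ProcessingConfig | None = None,
    out_dir: str | os.PathLike | None = None,
) -> BatchSummary:
    """Process every chromatogram in a folder and aggregate replicates.

    Files with extensions .txt/.arw/.tsv are processed in sorted order.
    When ``calibrants`` is given, samples failing calibration are
    excluded from aggregation (conservative) and listed in
    ``failed_samples``.  When ``out_dir`` is given, per-sample result
    tables, calibrated chromatograms and a summary table are written
    there with fixed 6-significant-digit formatting.
    """
    config = config or ProcessingConfig()
    input_dir = Path(input_dir)
    paths = sorted(
        p
        for p in input_dir.iterdir()
        if p.is_file() and p.suffix.lower() in CHROMATOGRAM_EXTENSIONS
    )
    if not paths:
        raise BatchError(f"no chromatogram files found in {input_dir}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    per_sample: dict[str, list[AnalyteResult]] = {}
    failed: list[tuple[str, str]] = []
    for path in paths:
        try:
            chrom = read_chromatogram(path)
            if calibrants is not None:
                chrom, _ = calibrate(
                    chrom,
                    calibrants,
                    min_sn=config.min_sn,
                    min_calibrants=config.min_calibrants,
                    background_window=config.background_window,
                    noise_points=config.baseline_points,
                )
                if out_dir is not None:
                    write_chromatogram(chrom, out_dir / f"{path.stem}_calibrated.tsv")
            results = quantify_chromatogram(chrom, analytes, config)
        except (ChromatogramError, CalibrationError, QuantitationError) as exc:
            log.warning("sample %s failed: %s", path.name, exc)
            failed.append((path.name, str(exc)))
            continue
        per_sample[chrom.sample_id] = results
        if out_dir is not None:
            write_results_table(results, out_dir / f"{path.stem}_results.tsv")
    if not per_sample:
        raise BatchError(
            "no sample could be processed: "
            + "; ".join(f"{name}: {reason}" for name, reason in failed)
        )
    summary = summarize(per_sample, analytes)
    if out_dir is not None:
        lines = ["name\tmean_area_rel\tsd_area_rel\tcv_percent\tn"]
        for s in summary:
            lines.append(
                f"{s.name}\t{_fmt(s.mean_area_rel)}\t{_fmt(s.sd_area_rel)}"
                f"\t{_fmt(s.cv_percent)}\t{s.n}"
            )
        (out_dir / "summary.tsv").write_text("\n".join(lines) + "\n")
    return BatchSummary(
        analytes=summary,
        n_samples=len(per_sample),
        failed_samples=failed,
        per_sample=per_sample,
    )


#: glycan peaks summed into the G2S2 group
G2S2_PEAKS = ("GP21", "GP22", "GP23", "GP24")
#: glycan peaks summed into the total-profile G1F group
G1F_TOTAL_PEAKS = ("GP8", "GP9")


def compute_fab_glycosylation(
    g2s2_total: float, g2s2_fab: float, g1f_total: float, g1f_fc: float
) -> float:
    """Fab-glycosylation percentage from glycoform fractions.

    Returns ``100 * (g2s2_total / g2s2_fab) / (g1f_total / g1f_fc)``.
    All inputs must be positive fractions.
    """
    for name, value in (
        ("g2s2_total", g2s2_total),
        ("g2s2_fab", g2s2_fab),
        ("g1f_total", g1f_total),
        ("g1f_fc", g1f_fc),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")
    return 100.0 * (g2s2_total / g2s2_fab) / (g1f_total / g1f_fc)


def fab_glycosylation_from_profiles(
    total_profile: Mapping[str, float],
    fab_profile: Mapping[str, float],
    g1f_fc: float,
    g2s2_fab_peaks: Sequence[str] = G2S2_PEAKS,
) -> float:
    """Compose the group fractions from named glycan peaks and apply Eq.

    ``total_profile`` and ``fab_profile`` map glycan peak names to
    relative areas; G2S2 sums GP21-GP24 and the total-profile G1F sums
    GP8+GP9.  ``g1f_fc`` comes from an external glycopeptide
    measurement.
    """
    g2s2_total = sum(total_profile.get(p, 0.0) for p in G2S2_PEAKS)
    g2s2_fab = sum(fab_profile.get(p, 0.0) for p in g2s2_fab_peaks)
    g1f_total = sum(total_profile.get(p, 0.0) for p in G1F_TOTAL_PEAKS)
    return compute_fab_glycosylation(g2s2_total, g2s2_fab, g1f_total, g1f_fc)


def export_overlay(
    chromatograms: Sequence[Chromatogram],
    path: str | os.PathLike,
    region: tuple[float, float] | None = None,
) -> None:
    """Write a static overlay plot of max-normalised chromatograms.

    Each trace is divided by its maximum intensity inside ``region``
    (whole trace when ``None``) so replicate profiles superimpose.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not chromatograms:
        raise ValueError("need at least one chromatogram to overlay")
    fig, ax = plt.subplots(figsize=(10, 4))
    for chrom in chromatograms:
        if region is None:
            t, y = chrom.time, chrom.intensity
        else:
            sub = chrom.slice(*region)
            t, y = sub.time, sub.intensity
        peak = float(np.max(y))
        if peak <= 0:
            raise ValueError(
                f"chromatogram {chrom.sample_id!r}: non-positive maximum, "
                "cannot normalise"
            )
        ax.plot(t, y / peak, linewidth=0.8, label=chrom.sample_id)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("normalised intensity")
    if len(chromatograms) <= 12:
        ax.legend(fontsize="x-small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
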
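"""Reading and writing chromatogram exports and peak lists.

Three text dialects are supported:

``plain_tsv``
    Two tab-separated columns, time (minutes) and intensity, one data
    point per line.  Lines starting with ``#`` are ignored.

``chromeleon_txt``
    A block of ``key: value`` metadata lines, a line starting with
    ``Chromatogram Data`` and then tab-separated data lines holding
    either ``time<TAB>intensity`` or ``time<TAB>step<TAB>intensity``.
    Decimal commas are accepted and normalised.

``empower_arw``
    Two tab-separated header lines (field names, then field values,
    typically including ``SampleName``) followed by tab-separated
    time/intensity pairs.  Decimal commas are accepted.

The vendor layouts vary between instrument configurations; the two
dialects implemented here are declared, documented approximations that
round-trip with the fixture writers in this module.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Dialect",
    "Chromatogram",
    "PeakDefinition",
    "ChromatogramError",
    "PeakListError",
    "read_chromatogram",
    "write_chromatogram",
    "read_peak_list",
    "write_peak_list",
]


class Dialect(str, enum.Enum):
    """Supported chromatogram text dialects."""

    CHROMELEON_TXT = "chromeleon_txt"
    EMPOWER_ARW = "empower_arw"
    PLAIN_TSV = "plain_tsv"


class ChromatogramError(ValueError):
    """Raised for unparseable or invalid chromatogram data."""


class PeakListError(ValueError):
    """Raised for unparseable peak-list files."""


@dataclass(frozen=True)
class Chromatogram:
    """A 2D chromatogram: paired time (minutes) and intensity vectors.

    Attributes
    ----------
    sample_id:
        Identifier for the injection; the file stem unless a header
        field provided a sample name.
    time:
        Strictly increasing time axis in minutes.
    intensity:
        Signal in arbitrary fluorescence units; may be negative after
        baseline subtraction.
    """

    sample_id: str
    time: np.ndarray
    intensity: np.ndarray
    source_path: str = ""
    dialect: Dialect = Dialect.PLAIN_TSV

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)
        if time.ndim != 1 or intensity.ndim != 1:
            raise ChromatogramError("time and intensity must be 1-D vectors")
        if time.size != intensity.size:
            raise ChromatogramError(
                f"time ({time.size}) and intensity ({intensity.size}) lengths differ"
            )
        if time.size < 2:
            raise ChromatogramError("a chromatogram needs at least 2 data points")
        if not np.all(np.isfinite(time)) or not np.all(np.isfinite(intensity)):
            raise ChromatogramError("time and intensity must be finite")
        if not np.all(np.diff(time) > 0):
            bad = int(np.argmax(np.diff(time) <= 0))
            raise ChromatogramError(
                f"time must be strictly increasing (violation after point {bad})"
            )

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def sampling_interval(self) -> float:
        """Median spacing between successive data points (minutes)."""
        return float(np.median(np.diff(self.time)))

    def slice(self, start: float, end: float) -> "Chromatogram":
        """Return the sub-chromatogram with ``start <= t <= end``."""
        mask = (self.time >= start) & (self.time <= end)
        if int(mask.sum()) < 2:
            raise ChromatogramError(
                f"region [{start}, {end}] contains fewer than 2 data points"
            )
        return Chromatogram(
            sample_id=self.sample_id,
            time=self.time[mask],
            intensity=self.intensity[mask],
            source_path=self.source_path,
            dialect=self.dialect,
        )

    def with_values(
        self,
        time: np.ndarray | None = None,
        intensity: np.ndarray | None = None,
    ) -> "Chromatogram":
        """Copy with replaced time and/or intensity vectors."""
        return Chromatogram(
            sample_id=self.sample_id,
            time=self.time if time is None else np.asarray(time, dtype=float),
            intensity=(
                self.intensity
                if intensity is None
                else np.asarray(intensity, dtype=float)
            ),
            source_path=self.source_path,
            dialect=self.dialect,
        )


@dataclass(frozen=True)
class PeakDefinition:
    """Named analyte window: expected retention time and half-width."""

    name: str
    tr_expected: float
    window: float

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise PeakListError(f"peak {self.name!r}: window must be > 0")
        if not self.tr_expected > 0:
            raise PeakListError(f"peak {self.name!r}: retention time must be > 0")

    @property
    def start(self) -> float:
        return self.tr_expected - self.window

    @property
    def end(self) -> float:
        return self.tr_expected + self.window


# ---------------------------------------------------------------------------
# parsing helpers


def _to_float(token: str, path: str, lineno: int) -> float:
    try:
        return float(token.replace(",", "."))
    except ValueError:
        raise ChromatogramError(
            f"{path}:{lineno}: cannot parse number from {token!r}"
        ) from None


def _is_pair_of_floats(line: str) -> bool:
    parts = line.split("\t")
    if len(parts) != 2:
        return False
    try:
        float(parts[0])
        float(parts[1])
    except ValueError:
        return False
    return True


def _parse_plain_tsv(lines: list[str], path: str) -> tuple[str | None, list, list]:
    times, values = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ChromatogramError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
            )
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise ChromatogramError(
                f"{path}:{lineno}: cannot parse data line {line!r}"
            ) from None
    return None, times, values


_CHROMELEON_MARKER = "chromatogram data"


def _parse_chromeleon(lines: list[str], path: str) -> tuple[str | None, list, list]:
    sample_id = None
    data_start = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.lower().startswith(_CHROMELEON_MARKER):
            data_start = lineno
            break
        if ":" in line:
            key, _, value = line.partition(":")
            if "sample" in key.lower() or "injection" == key.strip().lower():
                value = value.strip()
                if value:
                    sample_id = value
    if data_start is None:
        raise ChromatogramError(
            f"{path}: no 'Chromatogram Data' marker found (not a Chromeleon export?)"
        )
    times, values = [], []
    for lineno, raw in enumerate(lines[data_start:], start=data_start + 1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ChromatogramError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                f"got {len(parts)}"
            )
        first = parts[0].replace(",", ".")
        try:
            float(first)
        except ValueError:
            if not times:  # tolerate a single column-header row
                continue
            raise ChromatogramError(
                f"{path}:{lineno}: cannot parse data line {line!r}"
            ) from None
        times.append(_to_float(parts[0], path, lineno))
        values.append(_to_float(parts[-1], path, lineno))
    if not times:
        raise ChromatogramError(f"{path}: empty data block")
    return sample_id, times, values


def _parse_empower(lines: list[str], path: str) -> tuple[str | None, list, list]:
    stripped = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if len(stripped) < 3:
        raise ChromatogramError(f"{path}: too short for an Empower-style export")
    (_, names_line), (_, values_line) = stripped[0], stripped[1]
    names = [f.strip().strip('"') for f in names_line.split("\t")]
    values = [f.strip().strip('"') for f in values_line.split("\t")]
    sample_id = None
    header = dict(zip(names, values))
    for key in ("SampleName", "Sample Name", "sample_name"):
        if header.get(key):
            sample_id = header[key]
            break
    times, intens = [], []
    for lineno, line in stripped[2:]:
        parts = line.split("\t")
        if len(parts) != 2:
            raise ChromatogramError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
            )
        times.append(_to_float(parts[0], path, lineno))
        intens.append(_to_float(parts[1], path, lineno))
    if not times:
        raise ChromatogramError(f"{path}: empty data block")
    return sample_id, times, intens


_PARSERS = {
    Dialect.PLAIN_TSV: _parse_plain_tsv,
    Dialect.CHROMELEON_TXT: _parse_chromeleon,
    Dialect.EMPOWER_ARW: _parse_empower,
}


def _sniff_dialect(path: Path, lines: list[str]) -> Dialect:
    ext = path.suffix.lower()
    if ext == ".arw":
        return Dialect.EMPOWER_ARW
    head = [ln.strip() for ln in lines[:200] if ln.strip()]
    if any(ln.lower().startswith(_CHROMELEON_MARKER) for ln in head):
        return Dialect.CHROMELEON_TXT
    if head and not _is_pair_of_floats(head[0]) and not head[0].startswith("#"):
        # non-numeric leading line without a Chromeleon marker: assume Empower
        return Dialect.EMPOWER_ARW
    return Dialect.PLAIN_TSV


def read_chromatogram(
    path: str | os.PathLike, dialect: Dialect | str = "auto"
) -> Chromatogram:
    """Parse a chromatogram export into a :class:`Chromatogram`.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        One of :class:`Dialect` (or its string value) or ``"auto"`` to
        infer the dialect from the extension and then the content.
    """
    p = Path(path)
    text = p.read_text()
    lines = text.splitlines()
    if dialect == "auto":
        resolved = _sniff_dialect(p, lines)
    else:
        resolved = Dialect(dialect)
    sample_id, times, values = _PARSERS[resolved](lines, str(p))
    if not times:
        raise ChromatogramError(f"{p}: empty data block")
    return Chromatogram(
        sample_id=sample_id or p.stem,
        time=np.asarray(times, dtype=float),
        intensity=np.asarray(values, dtype=float),
        source_path=str(p),
        dialect=resolved,
    )


_FLOAT_FMT = "{:.12g}"


def write_chromatogram(
    chrom: Chromatogram,
    path: str | os.PathLike,
    dialect: Dialect | str = Dialect.PLAIN_TSV,
) -> None:
    """Write a chromatogram in any of the supported text dialects.

    Numbers are written with 12 significant digits so a write/read
    round trip preserves time and intensity to better than 1e-9
    relative.
    """
    dialect = Dialect(dialect)
    p = Path(path)
    rows = zip(chrom.time, chrom.intensity)
    if dialect is Dialect.PLAIN_TSV:
        lines = [
            f"{_FLOAT_FMT.format(t)}\t{_FLOAT_FMT.format(v)}" for t, v in rows
        ]
    elif dialect is Dialect.CHROMELEON_TXT:
        step = chrom.sampling_interval * 60.0  # seconds, cosmetic metadata
        header = [
            "Raw Data Export",
            f"Sample Name: {chrom.sample_id}",
            "Injection Volume: 10.0",
            "Dilution Factor: 1.0",
            "Detector: FLD",
            "Signal Unit: EU",
            "Time Unit: min",
            f"Data Points: {len(chrom)}",
            f"Start Time (min): {_FLOAT_FMT.format(chrom.time[0])}",
            f"End Time (min): {_FLOAT_FMT.format(chrom.time[-1])}",
            f"Average Step (s): {_FLOAT_FMT.format(step)}",
            "Chromatogram Data:",
        ]
        lines = header + [
            f"{_FLOAT_FMT.format(t)}\t{_FLOAT_FMT.format(step)}\t{_FLOAT_FMT.format(v)}"
            for t, v in rows
        ]
    elif dialect is Dialect.EMPOWER_ARW:
        lines = [
            '"SampleName"\t"Instrument Method Name"\t"Channel"',
            f'"{chrom.sample_id}"\t"HILIC-FLR"\t"FLR ChA"',
        ] + [f"{_FLOAT_FMT.format(t)}\t{_FLOAT_FMT.format(v)}" for t, v in rows]
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown dialect {dialect!r}")
    p.write_text("\n".join(lines) + "\n")


def read_peak_list(path: str | os.PathLike) -> list[PeakDefinition]:
    """Read a 3-column tab-separated peak list (name, t_r, half-window).

    Lines starting with ``#`` and blank lines are skipped; order is
    preserved.
    """
    p = Path(path)
    peaks: list[PeakDefinition] = []
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PeakListError(
                f"{p}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        name = parts[0].strip()
        try:
            tr = float(parts[1])
            window = float(parts[2])
        except ValueError:
            raise PeakListError(
                f"{p}:{lineno}: non-numeric retention time or window in {line!r}"
            ) from None
        peaks.append(PeakDefinition(name=name, tr_expected=tr, window=window))
    return peaks


def write_peak_list(peaks: Sequence[PeakDefinition], path: str | os.PathLike) -> None:
    """Write peak definitions in the 3-column tab-separated format."""
    lines = [
        f"{pk.name}\t{_FLOAT_FMT.format(pk.tr_expected)}\t{_FLOAT_FMT.format(pk.window)}"
        for pk in peaks
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
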
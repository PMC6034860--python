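"""Processing configuration shared by quantitation and batch runs."""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["ProcessingConfig", "load_config"]


@dataclass(frozen=True)
class ProcessingConfig:
    """Named processing settings for a batch run.

    Defaults follow the glycopeptide workflow: analysis region 11-25
    minutes, background window 1.0 min, order-1 baseline on 100 points,
    4 calibrants at minimum S/N 9, 1% detection cutoff.
    """

    start_tr: float = 11.0
    end_tr: float = 25.0
    background_window: float = 1.0
    baseline_order: int = 1
    baseline_points: int = 100
    min_calibrants: int = 4
    min_sn: float = 9.0
    cutoff_fraction: float = 0.01
    quant_window: float = 0.15
    subtract_background: bool = True

    def __post_init__(self) -> None:
        if not self.start_tr < self.end_tr:
            raise ValueError("start_tr must be smaller than end_tr")
        for name in (
            "background_window",
            "baseline_points",
            "min_calibrants",
            "min_sn",
            "cutoff_fraction",
            "quant_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def region(self) -> tuple[float, float]:
        return (self.start_tr, self.end_tr)


def load_config(path: str | os.PathLike) -> ProcessingConfig:
    """Load a :class:`ProcessingConfig` from a TOML file.

    Unknown keys raise, so typos in config files are caught early.
    """
    raw = tomllib.loads(Path(path).read_text())
    known = {f.name for f in fields(ProcessingConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ProcessingConfig(**raw)
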
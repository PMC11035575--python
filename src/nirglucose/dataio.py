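"""Reading, writing and aggregating sensor data; glucose unit conversion.

All tables are comma-delimited UTF-8 CSV with a header row. A frame log is
one CSV per acquisition with columns ``frame_index, voltage_V``; the sample
table carries one row per acquisition with the aggregated voltage, the
calibration voltages, the invasive reference value and the volunteer
covariates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SchemaError
from .simulate import SAMPLE_COLUMNS

__all__ = [
    "MGDL_PER_MMOL",
    "FrameSeries",
    "read_frame_log",
    "write_frame_log",
    "aggregate_frames",
    "mgdl_to_mmol",
    "mmol_to_mgdl",
    "load_sample_table",
    "write_sample_table",
    "validate_sample_table",
]

#: mg/dL per mmol/L. The study's own tables round-trip at 18.0 (not the
#: exact 18.0156 from the molar mass), so 18.0 is the default; pass
#: ``factor=`` to any converter to override.
MGDL_PER_MMOL = 18.0


@dataclass
class FrameSeries:
    """Ordered voltages of one acquisition."""

    voltages: np.ndarray
    site: str | None = None
    volunteer_id: str | None = None

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.size == 0:
            raise SchemaError("frame series must be non-empty")
        if not np.all(np.isfinite(self.voltages)):
            raise SchemaError("frame series contains non-finite voltages")

    def __len__(self):
        return len(self.voltages)


def read_frame_log(path: str | Path, site: str | None = None,
                   volunteer_id: str | None = None) -> FrameSeries:
    """Read one acquisition's frame log (``frame_index, voltage_V``).

    Order is preserved; a malformed row raises :class:`ParseError` naming
    the line number; a file with no data rows is rejected.
    """
    path = Path(path)
    voltages = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:  # header
                if len(row) < 2:
                    raise ParseError(path, lineno, "expected a two-column header")
                continue
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError(path, lineno, f"expected two columns, got {len(row)}")
            try:
                voltages.append(float(row[1]))
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-numeric voltage {row[1]!r}"
                ) from None
    if not voltages:
        raise ParseError(path, 1, "frame log contains no frames")
    return FrameSeries(np.array(voltages), site=site, volunteer_id=volunteer_id)


def write_frame_log(series: FrameSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "voltage_V"])
        for i, v in enumerate(series.voltages):
            writer.writerow([i, repr(float(v))])


def aggregate_frames(series: FrameSeries | np.ndarray, method: str = "mean") -> float:
    """Reduce a frame series to a single per-sample voltage.

    The arithmetic mean (default) is the minimum-variance reduction under
    i.i.d. Gaussian frame noise; the median is robust to spike artifacts.
    """
    voltages = series.voltages if isinstance(series, FrameSeries) else np.asarray(series, float)
    if voltages.size == 0:
        raise SchemaError("cannot aggregate an empty frame series")
    if method == "mean":
        return float(np.mean(voltages))
    if method == "median":
        return float(np.median(voltages))
    raise ConfigurationError(f"unknown aggregation method {method!r}")


def mgdl_to_mmol(value, factor: float = MGDL_PER_MMOL):
    """mg/dL -> mmol/L at full precision (round only when rendering)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ConfigurationError("glucose values must be > 0")
    out = arr / factor
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def mmol_to_mgdl(value, factor: float = MGDL_PER_MMOL):
    """mmol/L -> mg/dL, exact inverse of :func:`mgdl_to_mmol`."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ConfigurationError("glucose values must be > 0")
    out = arr * factor
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def validate_sample_table(table: pd.DataFrame) -> None:
    """Check the sample-table schema and physical invariants.

    Raises :class:`SchemaError` listing any missing column; rejects
    non-positive references and calibration rows with ``lv <= dc`` (the
    normalization denominator would be undefined).
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"sample table is missing required columns: {missing}")
    if (table["reference_mgdl"] <= 0).any():
        bad = table.index[table["reference_mgdl"] <= 0].tolist()
        raise SchemaError(f"non-positive reference glucose at rows {bad[:5]}")
    if (table["lv_volts"] <= table["dc_volts"]).any():
        bad = table.index[table["lv_volts"] <= table["dc_volts"]].tolist()
        raise SchemaError(
            f"bare-LED voltage must exceed dark current; violated at rows {bad[:5]}"
        )


def load_sample_table(path: str | Path, sort_by_reference: bool = False) -> pd.DataFrame:
    """Load and validate a sample table CSV.

    ``sort_by_reference=True`` returns the table in ascending order of the
    invasive reference value, the ordering the interval-based preprocessing
    assumes.
    """
    table = pd.read_csv(path)
    validate_sample_table(table)
    if sort_by_reference:
        table = table.sort_values("reference_mgdl", kind="mergesort").reset_index(drop=True)
    return table


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_sample_table(table)
    table.to_csv(path, index=False)
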
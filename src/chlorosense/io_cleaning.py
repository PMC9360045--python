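"""Reading, validation, cleaning and summary of raw buoy sensor tables.

A buoy record table holds one row per 15-minute sample per buoy with the five
monitored variables: water temperature (°C), electrical conductivity (µS/cm),
pH, system battery voltage (V) and chlorophyll-a fluorescence (µg/L).

Cleaning follows a two-tier out-of-range rule.  Each variable has configured
physical limits ``[lo, hi]``.  A value that strays beyond a limit by at most a
tolerance fraction (default 5%) of the span ``hi - lo`` is treated as a sensor
calibration artifact and snapped to the nearest boundary; a row holding a value
beyond that band, or a missing value, is judged a sensor failure and removed
whole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of a sensor record table
CANONICAL_COLUMNS = [
    "timestamp",
    "buoy_id",
    "temperature",
    "conductivity",
    "ph",
    "battery",
    "chlorophyll",
]

#: the five numeric sensor channels
NUMERIC_COLUMNS = ["temperature", "conductivity", "ph", "battery", "chlorophyll"]


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


@dataclass(frozen=True)
class ValidRanges:
    """Physical validity limits per variable plus the snap-band tolerance.

    ``limits`` maps each numeric column to ``(lo, hi)``.  ``tolerance`` is the
    fraction of the span ``hi - lo`` by which a value may exceed a limit and
    still be snapped back instead of discarded.

    The shipped defaults are plausible sensor ranges for a temperate freshwater
    reservoir; they are configuration, not measured instrument limits.
    """

    limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "temperature": (-5.0, 50.0),
            "conductivity": (0.0, 2000.0),
            "ph": (0.0, 14.0),
            "battery": (0.0, 20.0),
            "chlorophyll": (0.0, 500.0),
        }
    )
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.tolerance < 1.0:
            raise ValueError(f"tolerance must be in [0, 1), got {self.tolerance}")
        for name, (lo, hi) in self.limits.items():
            if not lo < hi:
                raise ValueError(f"limits for {name!r} must satisfy lo < hi, got ({lo}, {hi})")

    def span(self, name: str) -> float:
        lo, hi = self.limits[name]
        return hi - lo


@dataclass
class CleanReport:
    """Bookkeeping of a cleaning pass."""

    rows_in: int
    rows_snapped: dict[str, int]
    rows_removed: int

    @property
    def rows_kept(self) -> int:
        return self.rows_in - self.rows_removed

    @property
    def removal_fraction(self) -> float:
        return self.rows_removed / self.rows_in if self.rows_in else 0.0


def read_buoy_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a raw buoy CSV into a canonical, time-sorted record table.

    Parameters
    ----------
    path
        CSV file with a header row and ISO-8601 timestamps.
    schema
        Optional map from the file's column names to canonical names
        (``timestamp``, ``buoy_id``, ``temperature``, ``conductivity``,
        ``ph``, ``battery``, ``chlorophyll``).

    Returns
    -------
    DataFrame sorted by ``(buoy_id, timestamp)``.

    Raises
    ------
    SchemaError
        If a required column is missing or a ``(buoy_id, timestamp)`` pair is
        duplicated.
    ValueError
        If a timestamp fails to parse; the message names the offending row.
    """
    raw = pd.read_csv(path)
    if schema:
        raw = raw.rename(columns=schema)
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    table = raw[CANONICAL_COLUMNS].copy()
    parsed = pd.to_datetime(table["timestamp"], errors="coerce")
    if parsed.isna().any():
        bad = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(
            f"unparseable timestamp {table['timestamp'].iloc[bad]!r} at row {bad}"
        )
    table["timestamp"] = parsed
    dup = table.duplicated(subset=["buoy_id", "timestamp"])
    if dup.any():
        first = table.loc[dup, ["buoy_id", "timestamp"]].iloc[0]
        raise SchemaError(
            f"duplicate sample for buoy {first['buoy_id']!r} at {first['timestamp']}"
        )
    for col in NUMERIC_COLUMNS:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    return table.sort_values(["buoy_id", "timestamp"], kind="stable").reset_index(drop=True)


def clean_records(
    table: pd.DataFrame, ranges: ValidRanges | None = None
) -> tuple[pd.DataFrame, CleanReport]:
    """Snap near-limit values to their boundary and drop invalid rows.

    For each variable with limits ``[lo, hi]`` and span ``s = hi - lo``:
    values in ``(hi, hi + tol*s]`` become ``hi``, values in ``[lo - tol*s, lo)``
    become ``lo``.  Any row with a value beyond the tolerance band, or with a
    missing value in any numeric channel, is removed entirely.

    Row order and timestamps of kept rows are preserved; the operation is
    idempotent.
    """
    if ranges is None:
        ranges = ValidRanges()
    missing_cfg = [c for c in NUMERIC_COLUMNS if c not in ranges.limits]
    if missing_cfg:
        raise ValueError(f"ranges missing limits for: {missing_cfg}")

    n_in = len(table)
    snapped: dict[str, int] = {c: 0 for c in NUMERIC_COLUMNS}
    if n_in == 0:
        return table.copy(), CleanReport(rows_in=0, rows_snapped=snapped, rows_removed=0)

    out = table.copy()
    keep = np.ones(n_in, dtype=bool)
    for col in NUMERIC_COLUMNS:
        lo, hi = ranges.limits[col]
        band = ranges.tolerance * (hi - lo)
        vals = out[col].to_numpy(dtype=float)
        absent = np.isnan(vals)
        snap_hi = (vals > hi) & (vals <= hi + band)
        snap_lo = (vals < lo) & (vals >= lo - band)
        beyond = ~absent & ((vals > hi + band) | (vals < lo - band))
        vals[snap_hi] = hi
        vals[snap_lo] = lo
        out[col] = vals
        snapped[col] = int(snap_hi.sum() + snap_lo.sum())
        keep &= ~(absent | beyond)

    removed = int(n_in - keep.sum())
    report = CleanReport(rows_in=n_in, rows_snapped=snapped, rows_removed=removed)
    cleaned = out.loc[keep].reset_index(drop=True)
    if removed == n_in:
        logger.warning("cleaning removed every row (%d of %d)", removed, n_in)
    logger.info(
        "cleaning: %d rows in, %d removed (%.2f%%), snapped per variable: %s",
        n_in, removed, 100 * report.removal_fraction, snapped,
    )
    return cleaned, report


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Eight descriptive statistics per sensor channel.

    Returns a DataFrame indexed by ``count, mean, std, min, p25, p50, p75,
    max`` with one column per variable.  ``std`` is the sample (n-1) standard
    deviation.
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    stats = table[NUMERIC_COLUMNS].describe()
    stats.index = ["count", "mean", "std", "min", "p25", "p50", "p75", "max"]
    # a single-row table has undefined sample std; report 0 to keep tables numeric
    if len(table) == 1:
        stats.loc["std"] = 0.0
    return stats
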
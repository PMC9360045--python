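"""Moving-window feature augmentation, target aggregation and normalization.

The soft-sensor infers chlorophyll-a from four cheap input variables
(temperature, conductivity, pH, system battery).  Each input can be augmented
with five descriptive statistics (mean, std, median, min, max) computed over a
trailing 1-hour and/or 24-hour window, giving four input variants:

========== ======================== ========
variant    windows                  columns
========== ======================== ========
input_orig none                     4
input_hour 1 h                      24
input_day  24 h                     24
input_mix  1 h and 24 h             44
========== ======================== ========

The target can be the instantaneous chlorophyll-a reading or its trailing
1-hour / 24-hour mean or median (five output variants), which damps
fluorometer noise spikes.  All windows are trailing (causal): the statistic at
time ``t`` pools samples in ``(t - W, t]``, so no feature or target ever sees
the future.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import PowerTransformer

from .io_cleaning import NUMERIC_COLUMNS

#: raw sensor column -> canonical feature name
BASE_FEATURES = {
    "temperature": "Temperature",
    "conductivity": "Conductivity",
    "ph": "pH",
    "battery": "SystemBattery",
}

ROLLING_STATS = ["mean", "std", "median", "min", "max"]

WINDOWS = {"hour": pd.Timedelta(hours=1), "day": pd.Timedelta(hours=24)}

INPUT_VARIANTS = {
    "input_orig": (),
    "input_hour": ("hour",),
    "input_day": ("day",),
    "input_mix": ("hour", "day"),
}

#: output variant name -> (window name or None, statistic)
OUTPUT_VARIANTS = {
    "output_orig": (None, "identity"),
    "output_hour_mean": ("hour", "mean"),
    "output_hour_median": ("hour", "median"),
    "output_day_mean": ("day", "mean"),
    "output_day_median": ("day", "median"),
}


def variant_columns(variant: str) -> list[str]:
    """Canonical, ordered column names of an input variant."""
    if variant not in INPUT_VARIANTS:
        raise ValueError(f"unknown input variant {variant!r}; expected one of {list(INPUT_VARIANTS)}")
    cols = list(BASE_FEATURES.values())
    for window in INPUT_VARIANTS[variant]:
        for base in BASE_FEATURES.values():
            for stat in ROLLING_STATS:
                cols.append(f"{base}_{window}_{stat}")
    return cols


def rolling_stats(
    series: pd.Series, window: str | pd.Timedelta, stats=ROLLING_STATS
) -> pd.DataFrame:
    """Trailing-window descriptive statistics of a time-indexed series.

    For each timestamp ``t`` the statistics pool the samples with timestamps in
    ``(t - window, t]``; the window always contains at least the current
    sample.  ``std`` is the sample standard deviation, reported as 0 for a
    single-sample window.
    """
    unknown = [s for s in stats if s not in ROLLING_STATS]
    if unknown:
        raise ValueError(f"unknown statistics {unknown}; expected subset of {ROLLING_STATS}")
    if isinstance(window, str):
        window = WINDOWS[window]
    if not series.index.is_monotonic_increasing:
        raise ValueError("series must be time-sorted")
    roll = series.rolling(window, closed="right", min_periods=1)
    out = {}
    for stat in stats:
        col = getattr(roll, stat)()
        if stat == "std":
            col = col.fillna(0.0)
        out[stat] = col
    return pd.DataFrame(out)


def _per_buoy(table: pd.DataFrame, func) -> pd.DataFrame:
    """Apply ``func`` to each buoy's time-indexed sub-table, preserving row order."""
    pieces = []
    for _, grp in table.groupby("buoy_id", sort=False):
        sub = grp.set_index("timestamp")
        res = func(sub)
        res.index = grp.index
        pieces.append(res)
    return pd.concat(pieces).loc[table.index]


def build_input_variant(table: pd.DataFrame, variant: str) -> pd.DataFrame:
    """Build an input feature matrix from a cleaned record table.

    Returns a DataFrame with ``timestamp``, ``buoy_id`` and the variant's
    feature columns in canonical order.  Rolling windows are computed per buoy.
    """
    cols = variant_columns(variant)
    out = table[["timestamp", "buoy_id"]].copy()
    for raw, base in BASE_FEATURES.items():
        out[base] = table[raw].to_numpy()
    for window in INPUT_VARIANTS[variant]:
        for raw, base in BASE_FEATURES.items():
            stats = _per_buoy(table, lambda sub, r=raw: rolling_stats(sub[r], window))
            for stat in ROLLING_STATS:
                out[f"{base}_{window}_{stat}"] = stats[stat].to_numpy()
    out.attrs["variant"] = variant
    return out[["timestamp", "buoy_id", *cols]]


def build_output_variant(table: pd.DataFrame, variant: str) -> pd.Series:
    """Build the regression target for an output variant.

    ``output_orig`` is the raw chlorophyll-a channel; the aggregated variants
    are its trailing-window mean or median per buoy, aligned to each sample's
    timestamp.
    """
    if variant not in OUTPUT_VARIANTS:
        raise ValueError(f"unknown output variant {variant!r}; expected one of {list(OUTPUT_VARIANTS)}")
    if "chlorophyll" not in table.columns or table["chlorophyll"].isna().any():
        raise ValueError("table must be cleaned and carry a chlorophyll column")
    window, stat = OUTPUT_VARIANTS[variant]
    if window is None:
        target = table["chlorophyll"].copy()
    else:
        agg = _per_buoy(table, lambda sub: rolling_stats(sub["chlorophyll"], window, [stat]))
        target = agg[stat]
    target.name = variant
    return target


def enumerate_experiment_grid() -> list[tuple[str, str]]:
    """All input x output variant pairs, in a fixed deterministic order."""
    return list(itertools.product(INPUT_VARIANTS, OUTPUT_VARIANTS))


@dataclass
class NormalizerState:
    """Frozen per-column Yeo-Johnson + standardization parameters.

    The Yeo-Johnson power family is used because it is defined for
    non-positive values (sub-zero temperature or battery anomalies); a lambda
    of 1 is the identity point.  Standardization is to zero mean and unit
    (population) standard deviation on the fit data; a zero-variance column
    keeps scale 1.
    """

    columns: list[str]
    lambdas: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    fitted_on: str = ""

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Apply the frozen transform; never refits."""
        missing = [c for c in self.columns if c not in matrix.columns]
        if missing:
            raise ValueError(f"matrix missing normalized columns: {missing}")
        pt = PowerTransformer(method="yeo-johnson", standardize=False)
        pt.lambdas_ = self.lambdas
        pt.n_features_in_ = len(self.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            power = pt.transform(matrix[self.columns].to_numpy(dtype=float))
        scaled = (power - self.means) / self.scales
        out = matrix.copy()
        out[self.columns] = scaled
        return out


def fit_normalizer(train: pd.DataFrame, columns: list[str] | None = None, fitted_on: str = "") -> NormalizerState:
    """Fit the power-transform + standard-scaler state on training rows only.

    Call this on the training folds of a split and apply the returned state to
    validation/test rows; applying a state never refits, which is the
    anti-leakage contract of the normalization step.
    """
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty matrix")
    if columns is None:
        columns = [c for c in train.columns if c not in ("timestamp", "buoy_id")]
    X = train[columns].to_numpy(dtype=float)
    pt = PowerTransformer(method="yeo-johnson", standardize=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        power = pt.fit_transform(X)
    means = power.mean(axis=0)
    scales = power.std(axis=0)
    degenerate = scales == 0.0
    if degenerate.any():
        bad = [c for c, d in zip(columns, degenerate) if d]
        warnings.warn(f"zero-variance columns {bad}; standardization scale set to 1")
        scales = np.where(degenerate, 1.0, scales)
    return NormalizerState(
        columns=list(columns),
        lambdas=pt.lambdas_.copy(),
        means=means,
        scales=scales,
        fitted_on=fitted_on,
    )


def apply_normalizer(state: NormalizerState, matrix: pd.DataFrame) -> pd.DataFrame:
    """Functional alias for :meth:`NormalizerState.transform`."""
    return state.transform(matrix)
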
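"""Regression metrics, WHO level-1 alarm flags and per-month/buoy breakdowns.

The soft-sensor is judged on two tasks at once: tracking the chlorophyll-a
value (MAE, MSE, and MAE normalized by the target's spread) and raising the
WHO level-1 alarm when chlorophyll-a exceeds 10 µg/L (precision, recall, F1
and the confusion matrix of alarm flags).  Because bloom dynamics are
seasonal, metrics are also reported per calendar month — pooling every year's
occurrence of that month — and per buoy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: WHO alert level 1 threshold for chlorophyll-a, µg/L
LEVEL1_THRESHOLD = 10.0
#: additional WHO thresholds accepted for flag generation only
VIGILANCE_THRESHOLD = 1.0
LEVEL2_THRESHOLD = 50.0


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def alarm_flags(values, threshold: float = LEVEL1_THRESHOLD, inclusive: bool = False) -> np.ndarray:
    """Boolean alarm per sample.

    Default comparison is strictly greater than the threshold; pass
    ``inclusive=True`` for the "equal or higher" reading.  At the default
    10 µg/L level the boundary case is immaterial in practice but the choice
    is explicit.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("alarm flags require finite values")
    return v >= threshold if inclusive else v > threshold


def regression_metrics(y_true, y_pred) -> dict:
    """MAE, MSE and MAE/STD of one group of predictions.

    ``mae_over_std`` divides MAE by the sample standard deviation of the true
    targets; for a constant target group it is undefined and reported as NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if len(y_true) == 0:
        raise ValueError("cannot compute metrics of an empty group")
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    std = float(np.std(y_true, ddof=1)) if len(y_true) > 1 else 0.0
    return {
        "n": len(y_true),
        "mae": mae,
        "mse": mse,
        "mae_over_std": mae / std if std > 0 else np.nan,
    }


def classification_metrics(true_flags, pred_flags) -> dict:
    """Confusion matrix and precision/recall/F1 of alarm flags.

    A precision or recall with zero denominator is reported as NaN and the
    corresponding F1 as 0, keeping report tables machine-comparable.
    """
    t = np.asarray(true_flags, dtype=bool)
    p = np.asarray(pred_flags, dtype=bool)
    if len(t) != len(p):
        raise ValueError("flag series lengths differ")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    precision = tp / (tp + fp) if (tp + fp) > 0 else np.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "n": len(t),
        "confusion": ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def evaluate_group(y_true, y_pred, threshold: float = LEVEL1_THRESHOLD, inclusive: bool = False) -> dict:
    """Both metric families for one group of rows."""
    out = regression_metrics(y_true, y_pred)
    out.update(
        classification_metrics(
            alarm_flags(y_true, threshold, inclusive),
            alarm_flags(y_pred, threshold, inclusive),
        )
    )
    return out


def monthly_breakdown(
    oof: pd.DataFrame,
    threshold: float = LEVEL1_THRESHOLD,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Per-(buoy, calendar month) and per-buoy overall metric reports.

    ``oof`` is an out-of-fold prediction frame with ``timestamp``,
    ``buoy_id``, ``y_true`` and ``y_pred`` columns.  Month groups pool every
    year's occurrence of that calendar month.  A month with no rows for a
    buoy is emitted with count 0 and absent metrics, so a multi-year report
    always has 12 month rows plus one overall row per buoy.
    """
    required = {"timestamp", "buoy_id", "y_true", "y_pred"}
    missing = required - set(oof.columns)
    if missing:
        raise ValueError(f"out-of-fold frame missing columns: {sorted(missing)}")
    months = np.asarray(pd.DatetimeIndex(oof["timestamp"]).month)
    rows = []
    empty = {
        "n": 0, "mae": np.nan, "mse": np.nan, "mae_over_std": np.nan,
        "confusion": ConfusionMatrix(0, 0, 0, 0),
        "precision": np.nan, "recall": np.nan, "f1": np.nan,
    }
    for buoy in pd.unique(oof["buoy_id"]):
        in_buoy = (oof["buoy_id"] == buoy).to_numpy()
        for month in range(1, 13):
            sel = in_buoy & (months == month)
            if sel.any():
                rep = evaluate_group(
                    oof.loc[sel, "y_true"], oof.loc[sel, "y_pred"], threshold, inclusive
                )
            else:
                rep = dict(empty)
            rows.append({"buoy_id": buoy, "month": month, **rep})
        rows.append(
            {
                "buoy_id": buoy,
                "month": "overall",
                **evaluate_group(
                    oof.loc[in_buoy, "y_true"], oof.loc[in_buoy, "y_pred"], threshold, inclusive
                ),
            }
        )
    return pd.DataFrame(rows)
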
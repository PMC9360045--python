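"""The four soft-sensor regressor families and feature-importance analysis.

Families
--------
``lr``
    Linear regression with an L2 (ridge) penalty — the fast, interpretable
    linear reference.
``cart``
    A single unpruned binary regression tree grown to a maximum depth,
    splitting on squared-error reduction; leaves predict their training mean.
``rf``
    A bagged ensemble of such trees with per-split random feature subsets
    (one third of the features by default, the regression convention);
    predictions average the trees.
``baseline``
    The naive control: a constant equal to the training-set mean of the
    target.  Any model worth deploying must beat it.

The linear fit, tree growth and bagging are delegated to scikit-learn
estimators; this module owns the family/configuration surface, the attachment
of the frozen normalizer state, and the importance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.tree import DecisionTreeRegressor

from .features import NormalizerState

FAMILIES = ("lr", "cart", "rf", "baseline")

#: named feature subsets selected by cumulative random-forest importance
FEATURE_SUBSETS = {
    "3-AGG": ["pH_day_max", "Temperature_day_min", "SystemBattery_day_min"],
    "5-AGG": [
        "pH_day_max",
        "Temperature_day_min",
        "SystemBattery_day_min",
        "Conductivity_day_max",
        "pH_day_min",
    ],
}


@dataclass(frozen=True)
class HyperParamConfig:
    """A sampled hyperparameter configuration for one family."""

    family: str
    params: tuple[tuple[str, Any], ...] = ()

    def as_dict(self) -> dict[str, Any]:
        return dict(self.params)

    def complexity_key(self) -> tuple:
        """Sort key preferring simpler models on MAE ties."""
        p = self.as_dict()
        return (
            p.get("n_estimators", 0),
            p.get("max_depth", 0),
            p.get("alpha", 0.0),
        )


@dataclass
class TrainedModel:
    """A fitted regressor plus everything needed to replay its predictions."""

    family: str
    config: HyperParamConfig
    columns: list[str]
    estimator: Any = None
    training_mean: float | None = None
    normalizer: NormalizerState | None = None
    n_train: int = 0


def fit(
    family: str,
    config: HyperParamConfig,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    columns: list[str] | None = None,
    normalizer: NormalizerState | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """Fit one regressor of the given family.

    If ``normalizer`` is given, its frozen transform is applied to ``X``
    before fitting and stored on the model, so :func:`predict` replays the
    exact same transform on new rows.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if columns is None:
        columns = [c for c in X.columns if c not in ("timestamp", "buoy_id")]
    if len(X) == 0:
        raise ValueError("cannot fit on an empty matrix")
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError(f"X and y are misaligned: {len(X)} vs {len(y)} rows")
    params = config.as_dict()

    model = TrainedModel(
        family=family, config=config, columns=list(columns),
        normalizer=normalizer, n_train=len(X),
    )
    if normalizer is not None:
        X = normalizer.transform(X)
    values = X[columns].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("feature matrix contains absent values")

    if family == "baseline":
        model.training_mean = float(np.mean(y))
        return model
    if family == "lr":
        est = Ridge(alpha=params["alpha"])
    elif family == "cart":
        est = DecisionTreeRegressor(
            max_depth=params["max_depth"], min_samples_leaf=1, random_state=seed
        )
    else:  # rf
        est = RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            max_features=params.get("max_features", 1 / 3),
            bootstrap=params.get("bootstrap", True),
            min_samples_leaf=1,
            random_state=seed,
            n_jobs=1,
        )
    est.fit(values, y)
    model.estimator = est
    return model


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Predict chlorophyll-a (µg/L), one finite value per row.

    If the model carries a normalizer state it is applied (never refitted)
    before prediction.
    """
    feature_cols = [c for c in X.columns if c not in ("timestamp", "buoy_id")]
    missing = [c for c in model.columns if c not in X.columns]
    extra = [c for c in feature_cols if c not in model.columns]
    if missing or extra:
        raise ValueError(f"column mismatch: missing {missing}, extra {extra}")
    if model.family == "baseline":
        return np.full(len(X), model.training_mean, dtype=float)
    if model.normalizer is not None:
        X = model.normalizer.transform(X)
    return np.asarray(model.estimator.predict(X[model.columns].to_numpy(dtype=float)), dtype=float)


def importance(model: TrainedModel, X: pd.DataFrame, y: pd.Series | np.ndarray) -> pd.DataFrame:
    """Linear and nonlinear feature importance of a fitted random forest.

    Returns one row per feature with:

    ``pearson``
        Pearson correlation of the (raw) feature with the target — the linear
        view.
    ``rf_share``
        Normalized mean impurity-decrease importance from the forest — the
        nonlinear view; shares are non-negative and sum to 1.
    """
    if model.family != "rf":
        raise ValueError(f"importance analysis requires an rf model, got {model.family!r}")
    y = np.asarray(y, dtype=float)
    shares = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = shares.sum()
    if total > 0:
        shares = shares / total
    pearson = []
    for col in model.columns:
        v = X[col].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(y) == 0:
            pearson.append(np.nan)
        else:
            pearson.append(float(np.corrcoef(v, y)[0, 1]))
    return pd.DataFrame(
        {"feature": model.columns, "pearson": pearson, "rf_share": shares}
    ).sort_values("rf_share", ascending=False, kind="stable").reset_index(drop=True)


def subset_share(table: pd.DataFrame, subset: list[str]) -> float:
    """Cumulative ``rf_share`` of a named feature subset."""
    missing = [f for f in subset if f not in set(table["feature"])]
    if missing:
        raise KeyError(f"subset members absent from importance table: {missing}")
    return float(table.loc[table["feature"].isin(subset), "rf_share"].sum())


def restrict_features(X: pd.DataFrame, subset: list[str] | str) -> pd.DataFrame:
    """Keep only a feature subset (plus timestamp/buoy bookkeeping columns).

    ``subset`` may be a name from :data:`FEATURE_SUBSETS` or an explicit list.
    Column order follows the subset definition; the operation is idempotent.
    """
    if isinstance(subset, str):
        try:
            subset = FEATURE_SUBSETS[subset]
        except KeyError:
            raise KeyError(f"unknown feature subset {subset!r}; known: {list(FEATURE_SUBSETS)}")
    missing = [f for f in subset if f not in X.columns]
    if missing:
        raise KeyError(f"features not present in matrix: {missing}")
    keep = [c for c in ("timestamp", "buoy_id") if c in X.columns]
    return X[keep + list(subset)]
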
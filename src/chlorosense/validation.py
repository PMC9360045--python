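"""Order-preserving chunked K-fold validation with random hyperparameter search.

Because the buoy series is strongly seasonal, a shuffled train/test split
would leak near-duplicate neighbouring samples across the boundary and
overstate performance.  Instead the time-sorted dataset is divided into K
contiguous chunks (never shuffled).  Each sampled hyperparameter configuration
is scored by training K models, each on K-1 chunks with one chunk held out for
validation, and averaging the K validation MAEs.  Assembling each row's
prediction from the fold that held it out yields a full-coverage out-of-fold
prediction series that can be broken down by buoy and calendar month — with a
multi-year record every calendar month is tested on all of its yearly
occurrences, not just the last year's.

The per-fold normalizer is fitted on that fold's training chunks only, so no
validation statistic contaminates the preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as _models
from .features import fit_normalizer
from .models import FAMILIES, HyperParamConfig, TrainedModel

logger = logging.getLogger(__name__)

#: hyperparameter search ranges per family
SEARCH_SPACE = {
    "lr": {"alpha": (1e-4, 1.0)},              # L2 coefficient, log-uniform
    "cart": {"max_depth": (1, 500)},           # uniform integer
    "rf": {"max_depth": (1, 500), "n_estimators": (2, 200)},
    "baseline": {},
}


@dataclass(frozen=True)
class SplitPlan:
    """K contiguous chunks over a time-sorted dataset.

    ``bounds[k] = (start, stop)`` is a half-open row-index interval; fold k
    validates on chunk k and trains on all other chunks, preserving row order.
    """

    n_rows: int
    bounds: tuple[tuple[int, int], ...]

    @property
    def K(self) -> int:
        return len(self.bounds)

    def chunk_indices(self, k: int) -> np.ndarray:
        start, stop = self.bounds[k]
        return np.arange(start, stop)

    def train_indices(self, k: int) -> np.ndarray:
        """All rows outside chunk k, in original temporal order."""
        mask = np.ones(self.n_rows, dtype=bool)
        start, stop = self.bounds[k]
        mask[start:stop] = False
        return np.flatnonzero(mask)


def make_chunks(n_rows: int, K: int = 10) -> SplitPlan:
    """Partition ``n_rows`` time-ordered rows into K contiguous chunks.

    Chunk sizes differ by at most one row; the union of chunks covers every
    row exactly once.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    if n_rows < K:
        raise ValueError(f"cannot split {n_rows} rows into {K} chunks")
    edges = np.linspace(0, n_rows, K + 1).round().astype(int)
    bounds = tuple((int(edges[i]), int(edges[i + 1])) for i in range(K))
    return SplitPlan(n_rows=n_rows, bounds=bounds)


def sample_configs(family: str, n: int, seed: int) -> list[HyperParamConfig]:
    """Draw ``n`` random configurations for one family, reproducibly.

    The L2 coefficient is sampled log-uniformly (its range spans four
    decades); tree depths and estimator counts are uniform integers over
    their inclusive ranges.  The baseline family has no hyperparameters and
    yields ``n`` identical empty configs.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n):
        params: list[tuple[str, object]] = []
        for name, (lo, hi) in SEARCH_SPACE[family].items():
            if name == "alpha":
                params.append((name, float(np.exp(rng.uniform(np.log(lo), np.log(hi))))))
            else:
                params.append((name, int(rng.integers(lo, hi + 1))))
        configs.append(HyperParamConfig(family=family, params=tuple(params)))
    return configs


@dataclass
class SearchLeaderboard:
    """Ranking of sampled configurations by mean validation MAE."""

    family: str
    entries: list[dict] = field(default_factory=list)  # config, fold_maes, mean_mae, failed

    @property
    def ranked(self) -> list[dict]:
        ok = [e for e in self.entries if not e.get("failed")]
        return sorted(
            ok, key=lambda e: (e["mean_mae"], e["config"].complexity_key(), e["order"])
        )

    @property
    def best(self) -> dict:
        ranked = self.ranked
        if not ranked:
            raise RuntimeError("no successfully evaluated configuration")
        return ranked[0]


def _feature_columns(X: pd.DataFrame) -> list[str]:
    return [c for c in X.columns if c not in ("timestamp", "buoy_id")]


def _fit_fold(
    family: str,
    config: HyperParamConfig,
    X: pd.DataFrame,
    y: np.ndarray,
    plan: SplitPlan,
    k: int,
    seed: int | None,
) -> tuple[TrainedModel, np.ndarray]:
    """Train on fold k's training chunks and predict its validation chunk."""
    tr, va = plan.train_indices(k), plan.chunk_indices(k)
    X_tr = X.iloc[tr]
    norm = fit_normalizer(X_tr, columns=_feature_columns(X), fitted_on=f"fold-{k}")
    model = _models.fit(
        family, config, X_tr, y[tr],
        columns=norm.columns, normalizer=norm, seed=seed,
    )
    return model, _models.predict(model, X.iloc[va])


def run_search(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    family: str,
    plan: SplitPlan,
    n_configs: int = 25,
    seed: int = 0,
) -> SearchLeaderboard:
    """Random-search one family over the chunked folds.

    For each of ``n_configs`` sampled configurations, K models are trained
    (one per fold) and the configuration's score is the mean of the K
    validation-chunk MAEs.  A configuration whose fit fails on any fold is
    kept on the leaderboard but marked failed and excluded from ranking.
    """
    if plan.n_rows != len(X):
        raise ValueError("split plan was built for a different dataset size")
    y = np.asarray(y, dtype=float)
    board = SearchLeaderboard(family=family)
    for order, config in enumerate(sample_configs(family, n_configs, seed)):
        fold_maes = []
        failed = False
        for k in range(plan.K):
            try:
                _, pred = _fit_fold(family, config, X, y, plan, k, seed=seed + 7919 * k)
            except Exception:  # noqa: BLE001 - a failed fit voids the config, not the search
                logger.exception("config %s failed on fold %d", config, k)
                failed = True
                break
            va = plan.chunk_indices(k)
            fold_maes.append(float(np.mean(np.abs(y[va] - pred))))
        board.entries.append(
            {
                "config": config,
                "order": order,
                "fold_maes": fold_maes,
                "mean_mae": float(np.mean(fold_maes)) if not failed else np.nan,
                "failed": failed,
            }
        )
    return board


def assemble_oof(
    config: HyperParamConfig,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    plan: SplitPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Out-of-fold predictions for one configuration.

    Each row is predicted exactly once, by the fold model whose validation
    chunk contains it, so the predicting model never saw that row in
    training.  Returns a frame with ``timestamp``, ``buoy_id``, ``month``,
    ``fold``, ``y_true`` and ``y_pred`` aligned to the dataset's row order.
    """
    y = np.asarray(y, dtype=float)
    pred = np.full(plan.n_rows, np.nan)
    fold_of = np.full(plan.n_rows, -1)
    for k in range(plan.K):
        _, p = _fit_fold(config.family, config, X, y, plan, k, seed=seed + 7919 * k)
        va = plan.chunk_indices(k)
        pred[va] = p
        fold_of[va] = k
    if (fold_of < 0).any():
        raise RuntimeError("split plan left rows uncovered")  # violates SplitPlan invariant
    out = pd.DataFrame(
        {
            "timestamp": X["timestamp"].to_numpy(),
            "buoy_id": X["buoy_id"].to_numpy() if "buoy_id" in X else "all",
            "fold": fold_of,
            "y_true": y,
            "y_pred": pred,
        }
    )
    out["month"] = pd.DatetimeIndex(out["timestamp"]).month
    return out


def count_scheduled_fits(
    n_variants: int = 20, n_configs: int = 25, n_families: int = 3, K: int = 10
) -> dict[str, int]:
    """Combinatorial size of a full experiment grid, without training anything.

    A full run evaluates every (input, output) dataset variant with every
    sampled configuration of every searched family; each unique setting costs
    K model fits.
    """
    settings = n_variants * n_configs * n_families
    return {
        "variants": n_variants,
        "unique_settings": settings,
        "scheduled_fits": settings * K,
    }
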
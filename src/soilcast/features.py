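"""Gradient-boosted-tree feature ranking and backward elimination.

Greenhouse soil temperature depends on several coupled environmental
channels; training on all of them at once costs time and can hurt accuracy
when channels are irrelevant.  The selector here turns the raw multichannel
record into a supervised table (every channel at the previous time step as
features, soil temperature now as target), ranks the lagged features by
split-gain importance from a gradient-boosted tree regressor, then
backward-eliminates: starting from all features, repeatedly drop the
lowest-ranked remaining feature, refit, and record the validation RMSE.
The retained subset is the one with the minimum validation RMSE (ties go
to the smaller subset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from .series import MultivariateSeries

__all__ = ["FeatureRanking", "EliminationTrace", "lag_supervise",
           "rank_importance", "backward_eliminate", "make_gbt_estimator",
           "GradientBoostingFeatureSelector"]


@dataclass(frozen=True)
class FeatureRanking:
    """Feature names with normalized importances, sorted descending."""

    names: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        if any(b > a + 1e-12 for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("scores must be sorted descending")
        if abs(sum(self.scores) - 1.0) > 1e-6:
            raise ValueError("scores must be normalized to sum 1")


@dataclass(frozen=True)
class EliminationTrace:
    """Per-round record of the backward elimination: subset -> val RMSE."""

    subsets: tuple[tuple[str, ...], ...]
    rmse: tuple[float, ...]


def make_gbt_estimator(name: str = "lightgbm", seed: int = 0):
    """A gradient-boosted-tree regressor with default settings and gain
    importances (the pluggable ranking estimator)."""
    if name == "lightgbm":
        from lightgbm import LGBMRegressor
        return LGBMRegressor(importance_type="gain", random_state=seed,
                             verbose=-1, n_jobs=1)
    if name == "xgboost":
        from xgboost import XGBRegressor
        return XGBRegressor(importance_type="total_gain", random_state=seed,
                            n_jobs=1, verbosity=0)
    raise ValueError(f"unknown gradient-boosting estimator {name!r}")


def lag_supervise(series: MultivariateSeries, target_channel: str,
                  lag: int = 1) -> tuple[pd.DataFrame, pd.Series]:
    """Supervised table: all channels at t-lag as features, target at t.

    The first `lag` rows are dropped; feature columns are named
    ``<channel>_lag<lag>``.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(series) < lag + 1:
        raise ValueError(f"series length {len(series)} too short for lag {lag}")
    values = series.values
    features = values.iloc[:-lag].reset_index(drop=True)
    features.columns = [f"{c}_lag{lag}" for c in values.columns]
    target = values[target_channel].iloc[lag:].reset_index(drop=True)
    target.name = target_channel
    return features, target


def _importances(estimator, feature_names) -> np.ndarray:
    imp = getattr(estimator, "feature_importances_", None)
    if imp is None:
        raise ValueError("estimator exposes no feature_importances_")
    imp = np.asarray(imp, dtype=float)
    if len(imp) != len(feature_names):
        raise ValueError("importance vector length mismatch")
    return imp


def rank_importance(features: pd.DataFrame, target, estimator) -> FeatureRanking:
    """Fit the estimator and rank features by normalized split-gain importance.

    Ordering is by score descending with the column order as a stable
    tie-break, so the ranking is invariant to column permutation by name.
    """
    est = clone(estimator)
    est.fit(features, np.asarray(target, dtype=float))
    imp = _importances(est, features.columns)
    total = imp.sum()
    scores = imp / total if total > 0 else np.full(len(imp), 1.0 / len(imp))
    order = np.lexsort((features.columns.to_numpy(), -scores))
    return FeatureRanking(
        names=tuple(features.columns[i] for i in order),
        scores=tuple(float(scores[i]) for i in order))


def backward_eliminate(features: pd.DataFrame, target, ranking: FeatureRanking,
                       estimator, val_fraction: float = 0.2
                       ) -> tuple[EliminationTrace, tuple[str, ...]]:
    """Drop the lowest-ranked remaining feature round by round, refit, score.

    Each round fits on the chronological head and scores RMSE on the tail
    (``val_fraction``).  Returns the full trace (subset sizes n, n-1, ..., 1)
    and the subset with minimum validation RMSE; ties prefer the smaller
    subset.
    """
    if set(ranking.names) != set(features.columns):
        raise ValueError("ranking does not cover the feature set")
    y = np.asarray(target, dtype=float)
    n_val = max(int(round(val_fraction * len(features))), 1)
    if n_val >= len(features):
        raise ValueError("val_fraction leaves no training data")
    subsets, rmses = [], []
    current = list(ranking.names)
    while current:
        X = features[current]
        est = clone(estimator)
        est.fit(X.iloc[:-n_val], y[:-n_val])
        pred = est.predict(X.iloc[-n_val:])
        rmse = float(np.sqrt(np.mean((pred - y[-n_val:]) ** 2)))
        subsets.append(tuple(current))
        rmses.append(rmse)
        current = current[:-1]  # drop lowest-ranked remaining feature
    best = 0
    for i in range(1, len(rmses)):
        if rmses[i] <= rmses[best]:  # ties -> smaller (later) subset
            best = i
    return EliminationTrace(subsets=tuple(subsets), rmse=tuple(rmses)), subsets[best]


class GradientBoostingFeatureSelector(BaseEstimator):
    """Rank-then-eliminate feature selector over lagged channel features.

    Fitting ranks the columns of X by gain importance (the fixed initial
    ranking) and backward-eliminates prefixes of that ranking against
    validation RMSE.  ``get_support``/``transform`` follow the sklearn
    selector idiom.
    """

    def __init__(self, estimator="lightgbm", val_fraction=0.2, random_state=0):
        self.estimator = estimator
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _make_estimator(self):
        if isinstance(self.estimator, str):
            return make_gbt_estimator(
                self.estimator,
                seed=0 if self.random_state is None else int(self.random_state))
        return clone(self.estimator)

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in range(np.shape(X)[1])])
        est = self._make_estimator()
        self.ranking_ = rank_importance(X, y, est)
        self.trace_, self.selected_features_ = backward_eliminate(
            X, y, self.ranking_, est, val_fraction=self.val_fraction)
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.isin(self.feature_names_in_,
                                list(self.selected_features_))
        return self

    def get_support(self):
        return self.support_

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[list(self.selected_features_)]
        return np.asarray(X)[:, self.support_]

    def report(self) -> dict:
        """JSON-serializable ranking / trace / chosen-subset report."""
        return {
            "ranking": [{"feature": n, "importance": s}
                        for n, s in zip(self.ranking_.names, self.ranking_.scores)],
            "trace": [{"features": list(s), "val_rmse": r}
                      for s, r in zip(self.trace_.subsets, self.trace_.rmse)],
            "selected": list(self.selected_features_),
        }
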
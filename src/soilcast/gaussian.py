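"""Probabilistic forecasting heads and prediction-interval constructors.

The main model (the Gaussian-likelihood N-HiTS) carries two output channels
per horizon step — a mean head ``mu = w.h + b`` and a scale head
``sigma = softplus(w.h + b)`` floored at 1e-6 — each flowing through the
same hierarchical-interpolation machinery and summed across blocks.
Training minimizes the Gaussian negative log-likelihood of the observed
futures; prediction intervals at a chosen confidence level come from
Monte-Carlo sampling of the fitted per-step Gaussians, and the interval
median doubles as the point forecast.

Three comparison constructors are provided: kernel-density fitting of
validation residuals (error fitting), bootstrap resampling of those
residuals, and a three-head pinball-loss (quantile) variant of the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, clone
from sklearn.utils.validation import check_is_fitted

from . import _autodiff as A
from ._autodiff import Tensor
from .nhits import _BaseNHiTS, NHiTSRegressor

__all__ = [
    "GaussianForecast", "IntervalForecast", "SIGMA_FLOOR",
    "gaussian_heads", "gaussian_nll", "mc_intervals", "pinball_loss",
    "interval_from_errors",
    "NHiTSGaussianForecaster", "NHiTSQuantileForecaster",
    "ResidualIntervalForecaster",
]

SIGMA_FLOOR = 1e-6


class GaussianForecast(NamedTuple):
    """Per-horizon-step Gaussian predictive parameters (scaled target units)."""

    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class IntervalForecast:
    """Per-step (lower, median, upper) bounds at a stated confidence level."""

    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray
    level: float = 0.90

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.median = np.asarray(self.median, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")
        if (np.any(self.lower > self.median + 1e-12)
                or np.any(self.median > self.upper + 1e-12)):
            raise ValueError("interval ordering lower <= median <= upper violated")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.where(x > 30.0, x, np.log1p(np.exp(np.minimum(x, 30.0))))


def gaussian_heads(ht, w_mu, b_mu, w_sigma, b_sigma,
                   floor: float = SIGMA_FLOOR) -> GaussianForecast:
    """Map a hidden representation through the two Gaussian output heads.

    ``mu`` is affine in ``ht``; ``sigma`` is softplus of an affine map,
    floored so it can never reach zero.
    """
    ht = np.asarray(ht, dtype=float)
    if not np.all(np.isfinite(ht)):
        raise ValueError("hidden representation contains non-finite values")
    mu = ht @ np.asarray(w_mu) + b_mu
    sigma = _softplus(ht @ np.asarray(w_sigma) + b_sigma) + floor
    return GaussianForecast(mu=np.asarray(mu), sigma=np.asarray(sigma))


def gaussian_nll(future_targets, forecast: GaussianForecast) -> float:
    """Mean per-step Gaussian negative log-likelihood of observed futures."""
    c = np.asarray(future_targets, dtype=float)
    mu, sigma = np.asarray(forecast.mu, float), np.asarray(forecast.sigma, float)
    if c.shape != mu.shape:
        raise ValueError("targets and forecast lengths differ")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    return float(np.mean(0.5 * np.log(2 * np.pi * sigma**2)
                         + (c - mu) ** 2 / (2 * sigma**2)))


def mc_intervals(forecast: GaussianForecast, n_samples: int = 500,
                 level: float = 0.90, seed: int | None = 0) -> IntervalForecast:
    """Monte-Carlo prediction interval from per-step Gaussian parameters.

    Draws ``n_samples`` per step (independently across steps) and takes the
    empirical (1-level)/2, 50% and 1-(1-level)/2 quantiles.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    mu = np.asarray(forecast.mu, float)
    sigma = np.asarray(forecast.sigma, float)
    draws = rng.normal(loc=mu, scale=sigma, size=(n_samples,) + mu.shape)
    alpha = (1.0 - level) / 2.0
    lo, med, hi = np.quantile(draws, [alpha, 0.5, 1.0 - alpha], axis=0)
    return IntervalForecast(lower=lo, median=med, upper=hi, level=level)


def pinball_loss(future_targets, prediction, q: float) -> float:
    """Mean pinball (quantile) loss at quantile q."""
    if not 0.0 < q < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    c = np.asarray(future_targets, dtype=float)
    p = np.asarray(prediction, dtype=float)
    diff = c - p
    return float(np.mean(q * np.maximum(diff, 0.0)
                         + (1.0 - q) * np.maximum(-diff, 0.0)))


# ---------------------------------------------------------------------------
# training losses on the autodiff tape
# ---------------------------------------------------------------------------

def gaussian_nll_loss(outputs: list[Tensor], y: np.ndarray) -> Tensor:
    """Tape version of the Gaussian NLL over (mu, pre-sigma) output channels."""
    mu, pre_sigma = outputs
    sigma = A.add(A.softplus(pre_sigma), SIGMA_FLOOR)
    diff = A.sub(Tensor(y), mu)
    quad = A.div(A.mul(diff, diff), A.mul(A.mul(sigma, sigma), 2.0))
    return A.add(A.mean(A.add(A.log(sigma), quad)), 0.5 * np.log(2.0 * np.pi))


def make_quantile_loss(quantiles):
    """Tape pinball loss summed over the three quantile output channels."""

    def loss_fn(outputs: list[Tensor], y: np.ndarray) -> Tensor:
        yt = Tensor(y)
        total = None
        for out, q in zip(outputs, quantiles):
            diff = A.sub(yt, out)
            term = A.mean(A.add(A.mul(A.relu(diff), q),
                                A.mul(A.relu(A.mul(diff, -1.0)), 1.0 - q)))
            total = term if total is None else A.add(total, term)
        return total

    return loss_fn


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class NHiTSGaussianForecaster(_BaseNHiTS):
    """N-HiTS with a Gaussian likelihood head (the package's main model).

    Two output channels per horizon step (mean and pre-softplus scale) flow
    through the hierarchical interpolation and are summed across blocks;
    residual backcasting acts on the target channel.  ``predict`` returns
    the Monte-Carlo interval median as the point forecast.
    """

    _out_channels = 2

    def __init__(self, lookback=12, n_stacks=3, n_blocks=1, mlp_units=128,
                 pool_kernel_sizes=(4, 2, 1), downsample_factors=(4, 2, 1),
                 learning_rate=1e-3, batch_size=32, max_epochs=500,
                 patience=50, validation_fraction=0.15, random_state=0,
                 level=0.90, n_samples=500):
        super().__init__(lookback=lookback, n_stacks=n_stacks,
                         n_blocks=n_blocks, mlp_units=mlp_units,
                         pool_kernel_sizes=pool_kernel_sizes,
                         downsample_factors=downsample_factors,
                         learning_rate=learning_rate, batch_size=batch_size,
                         max_epochs=max_epochs, patience=patience,
                         validation_fraction=validation_fraction,
                         random_state=random_state)
        self.level = level
        self.n_samples = n_samples

    def _loss_fn(self):
        return gaussian_nll_loss

    def predict_dist(self, X) -> GaussianForecast:
        """Per-sample (mu, sigma) of the predictive Gaussian, shape (n, H)."""
        outs, _ = self._forward(X)
        mu = outs[0].data
        sigma = _softplus(outs[1].data) + SIGMA_FLOOR
        return GaussianForecast(mu=mu, sigma=sigma)

    def predict_interval(self, X, level=None, n_samples=None,
                         seed=None) -> IntervalForecast:
        level = self.level if level is None else level
        n_samples = self.n_samples if n_samples is None else n_samples
        if seed is None:
            seed = 0 if self.random_state is None else int(self.random_state)
        dist = self.predict_dist(X)
        return mc_intervals(dist, n_samples=n_samples, level=level, seed=seed)

    def predict(self, X):
        """Point forecast = median of the Monte-Carlo forecasting interval."""
        med = self.predict_interval(X).median
        return med.ravel() if self._y_was_1d else med


class NHiTSQuantileForecaster(_BaseNHiTS):
    """N-HiTS trained with pinball loss at three quantiles (interval baseline)."""

    _out_channels = 3

    def __init__(self, lookback=12, n_stacks=3, n_blocks=1, mlp_units=128,
                 pool_kernel_sizes=(4, 2, 1), downsample_factors=(4, 2, 1),
                 learning_rate=1e-3, batch_size=32, max_epochs=500,
                 patience=50, validation_fraction=0.15, random_state=0,
                 level=0.90):
        super().__init__(lookback=lookback, n_stacks=n_stacks,
                         n_blocks=n_blocks, mlp_units=mlp_units,
                         pool_kernel_sizes=pool_kernel_sizes,
                         downsample_factors=downsample_factors,
                         learning_rate=learning_rate, batch_size=batch_size,
                         max_epochs=max_epochs, patience=patience,
                         validation_fraction=validation_fraction,
                         random_state=random_state)
        self.level = level

    @property
    def quantiles(self):
        alpha = (1.0 - self.level) / 2.0
        return (alpha, 0.5, 1.0 - alpha)

    def _loss_fn(self):
        return make_quantile_loss(self.quantiles)

    def predict_interval(self, X, **_) -> IntervalForecast:
        outs, _ = self._forward(X)
        heads = np.stack([o.data for o in outs])     # (3, n, H)
        heads = np.sort(heads, axis=0)               # enforce lo <= med <= hi
        return IntervalForecast(lower=heads[0], median=heads[1],
                                upper=heads[2], level=self.level)

    def predict(self, X):
        med = self.predict_interval(X).median
        return med.ravel() if self._y_was_1d else med


# ---------------------------------------------------------------------------
# residual-based interval constructors (error fitting / bootstrap)
# ---------------------------------------------------------------------------

def _kde_quantiles(residuals: np.ndarray, probs) -> np.ndarray:
    """Quantiles of a Gaussian-kernel density (Silverman bandwidth) fit."""
    if np.ptp(residuals) == 0.0:
        return np.full(len(probs), residuals[0])
    kde = gaussian_kde(residuals, bw_method="silverman")
    bw = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(residuals.min() - 4 * bw, residuals.max() + 4 * bw, 2001)
    pdf = kde(grid)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(probs, cdf, grid)


def interval_from_errors(val_predictions, val_observed,
                         method: str = "error_fit", level: float = 0.90,
                         n_resamples: int = 2000, seed: int = 0):
    """Build an interval constructor from per-step validation residuals.

    ``error_fit`` fits a Gaussian-kernel density (Silverman bandwidth) to
    each horizon step's residual pool and takes its (1-level)/2 and
    1-(1-level)/2 quantiles; ``bootstrap`` takes the same quantiles of the
    pooled resampled empirical residuals (seeded).  Returns a callable that
    maps point forecasts (n, H) to an :class:`IntervalForecast`, plus the
    per-step offsets (H, 3).
    """
    pred = np.atleast_2d(np.asarray(val_predictions, dtype=float))
    obs = np.atleast_2d(np.asarray(val_observed, dtype=float))
    if pred.shape != obs.shape:
        raise ValueError("validation predictions and observations differ in shape")
    if pred.shape[0] < 10:
        raise ValueError("need at least 10 validation residuals per step")
    if method not in ("error_fit", "bootstrap"):
        raise ValueError(f"unknown method {method!r}")
    resid = obs - pred                              # (n, H)
    alpha = (1.0 - level) / 2.0
    probs = np.array([alpha, 0.5, 1.0 - alpha])
    rng = np.random.default_rng(seed)
    offsets = np.empty((resid.shape[1], 3))
    for j in range(resid.shape[1]):
        pool = resid[:, j]
        if method == "error_fit":
            offsets[j] = _kde_quantiles(pool, probs)
        else:
            draws = rng.choice(pool, size=(n_resamples, pool.size), replace=True)
            offsets[j] = np.quantile(draws.ravel(), probs)

    def constructor(point_forecasts) -> IntervalForecast:
        p = np.atleast_2d(np.asarray(point_forecasts, dtype=float))
        return IntervalForecast(lower=p + offsets[:, 0],
                                median=p + offsets[:, 1],
                                upper=p + offsets[:, 2], level=level)

    return constructor, offsets


class ResidualIntervalForecaster(BaseEstimator):
    """Point forecaster wrapped with a residual-based interval constructor.

    Fits the base point forecaster on the head of the data, computes
    per-horizon-step residuals on a held-out calibration tail (or an
    explicit calibration set), and builds intervals by error fitting or
    bootstrap of those residuals.
    """

    def __init__(self, base_estimator=None, method="error_fit", level=0.90,
                 calibration_fraction=0.2, n_resamples=2000, random_state=0):
        self.base_estimator = base_estimator
        self.method = method
        self.level = level
        self.calibration_fraction = calibration_fraction
        self.n_resamples = n_resamples
        self.random_state = random_state

    def fit(self, X, y, X_cal=None, y_cal=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(len(X), -1)  # always 2D
        base = (NHiTSRegressor() if self.base_estimator is None
                else clone(self.base_estimator))
        if X_cal is None:
            n_cal = max(int(round(self.calibration_fraction * len(X))), 10)
            if n_cal >= len(X):
                raise ValueError("not enough data for a calibration tail")
            X, X_cal = X[:-n_cal], X[-n_cal:]
            y, y_cal = y[:-n_cal], y[-n_cal:]
        else:
            y_cal = np.asarray(y_cal, dtype=float).reshape(len(X_cal), -1)
        base.fit(X, y)
        self.base_estimator_ = base
        pred_cal = np.asarray(base.predict(X_cal)).reshape(len(X_cal), -1)
        self.constructor_, self.offsets_ = interval_from_errors(
            pred_cal, y_cal, method=self.method, level=self.level,
            n_resamples=self.n_resamples,
            seed=0 if self.random_state is None else int(self.random_state))
        return self

    def predict(self, X):
        check_is_fitted(self, "base_estimator_")
        return self.base_estimator_.predict(X)

    def predict_interval(self, X) -> IntervalForecast:
        check_is_fitted(self, "constructor_")
        pred = np.asarray(self.base_estimator_.predict(X)).reshape(len(X), -1)
        return self.constructor_(pred)
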
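"""Point and interval forecast quality metrics.

Point forecasts are scored with RMSE, MAE and MAPE.  Interval forecasts are
scored with the standard prediction-interval quartet:

* PICP  — fraction of observations inside their (closed) interval;
* PINAW — mean interval width, normalized by the target range A;
* PINRW — root-mean-square interval width, normalized by A;
* CWC   — coverage-width criterion:  PINAW * (1 + gamma * exp(-eta*(PICP - mu)))
          with gamma = 0 when PICP >= mu (coverage adequate) and 1 otherwise,
          so undercovering intervals are exponentially penalized.

A is the normalization range of the target channel (xmax - xmin of the
training partition); mu defaults to 0.80 and eta to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PointMetrics", "IntervalMetricsConfig", "IntervalMetrics",
           "point_metrics", "interval_metrics"]

_MAPE_GUARD = 1e-8


@dataclass(frozen=True)
class PointMetrics:
    rmse: float
    mae: float
    mape: float  # percent

    def as_dict(self) -> dict[str, float]:
        return {"RMSE": self.rmse, "MAE": self.mae, "MAPE": self.mape}


@dataclass(frozen=True)
class IntervalMetricsConfig:
    """Normalization range A, PICP threshold mu and penalty coefficient eta."""

    A: float
    mu_threshold: float = 0.80
    eta: float = 1.0

    def __post_init__(self):
        if not self.A > 0:
            raise ValueError("normalization range A must be > 0")
        if not 0.0 < self.mu_threshold < 1.0:
            raise ValueError("mu_threshold must be in (0, 1)")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")


@dataclass(frozen=True)
class IntervalMetrics:
    picp: float
    pinaw: float
    pinrw: float
    cwc: float

    def as_dict(self) -> dict[str, float]:
        return {"PICP": self.picp, "PINAW": self.pinaw,
                "PINRW": self.pinrw, "CWC": self.cwc}


def point_metrics(predicted, observed) -> PointMetrics:
    """RMSE, MAE and MAPE (in %) of a point forecast against observations."""
    Y = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if Y.shape != y.shape or Y.size == 0:
        raise ValueError("predicted and observed must have equal nonzero length")
    if np.any(np.abs(y) < _MAPE_GUARD):
        raise ValueError("MAPE undefined: an observed value is (near) zero")
    err = Y - y
    return PointMetrics(
        rmse=float(np.sqrt(np.mean(err**2))),
        mae=float(np.mean(np.abs(err))),
        mape=float(100.0 * np.mean(np.abs(err / y))),
    )


def interval_metrics(observed, lower, upper,
                     cfg: IntervalMetricsConfig) -> IntervalMetrics:
    """PICP/PINAW/PINRW/CWC of prediction intervals against observations.

    Coverage uses the closed interval: boundary hits count as covered.
    """
    y = np.asarray(observed, dtype=float).ravel()
    L = np.asarray(lower, dtype=float).ravel()
    U = np.asarray(upper, dtype=float).ravel()
    if not (y.shape == L.shape == U.shape) or y.size == 0:
        raise ValueError("observed, lower, upper must have equal nonzero length")
    if np.any(L > U):
        raise ValueError("lower bound exceeds upper bound")
    width = U - L
    picp = float(np.mean((y >= L) & (y <= U)))
    pinaw = float(np.mean(width) / cfg.A)
    pinrw = float(np.sqrt(np.mean(width**2)) / cfg.A)
    gamma = 0.0 if picp >= cfg.mu_threshold else 1.0
    cwc = pinaw * (1.0 + gamma * np.exp(-cfg.eta * (picp - cfg.mu_threshold)))
    return IntervalMetrics(picp=picp, pinaw=pinaw, pinrw=pinrw, cwc=float(cwc))
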
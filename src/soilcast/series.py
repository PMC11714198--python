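"""Sensor time-series I/O, gap repair, scaling, splitting and windowing.

The package works on uniformly sampled multichannel greenhouse sensor logs
(default cadence: one record every 20 minutes).  This module reads such logs
from CSV, repairs missing cells by linear interpolation between the nearest
observed neighbours, min-max scales each channel with statistics fitted on
the training partition only, splits the record chronologically into
train/validation/test blocks, and slices it into supervised
(history, future) window samples for direct multi-step forecasting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultivariateSeries",
    "ScalingStats",
    "SplitSpec",
    "WindowSample",
    "read_series",
    "fill_missing_linear",
    "fit_apply_minmax",
    "chronological_split",
    "make_windows",
    "windows_to_arrays",
]


@dataclass
class MultivariateSeries:
    """A uniformly spaced, timestamped multichannel record with missing mask.

    ``values`` holds one column per named channel; ``missing_mask`` is the
    per-cell boolean flag of originally missing observations (True = missing).
    """

    timestamps: pd.DatetimeIndex
    values: pd.DataFrame
    missing_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    interval_minutes: float = 20.0

    def __post_init__(self):
        if self.missing_mask is None:
            self.missing_mask = self.values.isna()
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if self.values.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        self.values.index = self.timestamps
        self.missing_mask.index = self.timestamps

    @property
    def channel_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.timestamps)

    def channel(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def iloc_slice(self, start: int, stop: int) -> "MultivariateSeries":
        """Positional sub-series [start, stop) (used for partition blocks)."""
        return MultivariateSeries(
            timestamps=self.timestamps[start:stop],
            values=self.values.iloc[start:stop].reset_index(drop=True),
            missing_mask=self.missing_mask.iloc[start:stop].reset_index(drop=True),
            interval_minutes=self.interval_minutes,
        )

    def to_csv(self, path, timestamp_column: str = "timestamp") -> None:
        frame = self.values.copy()
        frame.insert(0, timestamp_column, self.timestamps)
        frame.to_csv(path, index=False)


@dataclass
class ScalingStats:
    """Per-channel min/max used for min-max normalization x' = (x-min)/(max-min)."""

    xmin: dict[str, float]
    xmax: dict[str, float]

    def __post_init__(self):
        for name in self.xmin:
            if not self.xmax[name] > self.xmin[name]:
                raise ValueError(f"channel {name!r} is constant (xmax == xmin)")

    def range(self, channel: str) -> float:
        """Normalization range A = xmax - xmin of a channel, in its units."""
        return self.xmax[channel] - self.xmin[channel]

    def transform(self, values: pd.DataFrame) -> pd.DataFrame:
        out = values.copy()
        for name in out.columns:
            out[name] = (out[name] - self.xmin[name]) / self.range(name)
        return out

    def inverse(self, channel: str, scaled) -> np.ndarray:
        return np.asarray(scaled) * self.range(channel) + self.xmin[channel]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"xmin": self.xmin, "xmax": self.xmax}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScalingStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(xmin=d["xmin"], xmax=d["xmax"])


class SplitSpec(NamedTuple):
    """Resolved chronological train/validation/test block sizes."""

    n_train: int
    n_val: int
    n_test: int


class WindowSample(NamedTuple):
    """One supervised sample: lookback history plus the future to forecast."""

    history_targets: np.ndarray     # (T0,)
    history_covariates: np.ndarray  # (T0, d); d may be 0
    future_targets: np.ndarray      # (H,)


def read_series(path, timestamp_column: str = "timestamp",
                interval_minutes: float | None = None) -> MultivariateSeries:
    """Read a sensor CSV log into a :class:`MultivariateSeries`.

    Rows are sorted by timestamp; spacing must be uniform afterwards. Empty
    cells and the token ``NaN`` are flagged as missing in ``missing_mask``.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: file contains no data rows")
    if timestamp_column not in frame.columns:
        raise ValueError(f"{path}: no {timestamp_column!r} column in header")
    ts = pd.to_datetime(frame[timestamp_column])
    order = np.argsort(ts.to_numpy(), kind="stable")
    frame = frame.iloc[order].reset_index(drop=True)
    ts = pd.DatetimeIndex(ts.iloc[order]).tz_localize(None)

    if len(ts) > 1:
        deltas = np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(float)
        if not np.allclose(deltas, deltas[0]):
            bad = int(np.argmax(~np.isclose(deltas, deltas[0])))
            raise ValueError(
                "nonuniform spacing: gap between rows "
                f"{bad} and {bad + 1} ({ts[bad]} -> {ts[bad + 1]}) is "
                f"{deltas[bad] / 60:.1f} min, expected {deltas[0] / 60:.1f} min"
            )
        inferred = deltas[0] / 60.0
    else:
        inferred = interval_minutes or 20.0

    values = frame.drop(columns=[timestamp_column]).astype(float)
    return MultivariateSeries(
        timestamps=ts,
        values=values,
        interval_minutes=interval_minutes or inferred,
    )


def fill_missing_linear(series: MultivariateSeries) -> MultivariateSeries:
    """Repair missing cells by linear interpolation between observed neighbours.

    Interior gaps are filled with the straight line through the nearest
    observed values on each side (exact on a uniform grid); leading and
    trailing gaps take the nearest observed value.  The returned series has
    an all-clear missing mask.
    """
    filled = series.values.copy()
    for name in filled.columns:
        col = filled[name]
        if col.notna().sum() == 0:
            raise ValueError(f"channel {name!r} has no observed values")
        filled[name] = col.interpolate(method="linear", limit_direction="both",
                                       limit_area=None)
    return MultivariateSeries(
        timestamps=series.timestamps,
        values=filled,
        missing_mask=pd.DataFrame(False, index=series.timestamps,
                                  columns=filled.columns),
        interval_minutes=series.interval_minutes,
    )


def fit_apply_minmax(series: MultivariateSeries,
                     n_fit: int) -> tuple[MultivariateSeries, ScalingStats]:
    """Min-max scale every channel using statistics from the first *n_fit* rows.

    Fitting on the leading (training) block only keeps validation and test
    data out of the scaling statistics.  Returns the scaled series and the
    fitted :class:`ScalingStats` (whose target-channel range is the
    normalization constant A used by the interval-width metrics).
    """
    if not 0 < n_fit <= len(series):
        raise ValueError("n_fit must be in (0, len(series)]")
    head = series.values.iloc[:n_fit]
    stats = ScalingStats(
        xmin={c: float(head[c].min()) for c in series.channel_names},
        xmax={c: float(head[c].max()) for c in series.channel_names},
    )
    scaled = MultivariateSeries(
        timestamps=series.timestamps,
        values=stats.transform(series.values),
        missing_mask=series.missing_mask.copy(),
        interval_minutes=series.interval_minutes,
    )
    return scaled, stats


def chronological_split(n: int, ratios: Sequence[float] = (0.70, 0.15, 0.15)
                        ) -> SplitSpec:
    """Resolve train/val/test counts for a chronological split of *n* points.

    ``n_train = floor(r_train*n)``, ``n_val = ceil(r_val*n)`` and the test
    block takes the remainder — the rule that maps 5767 points at
    70/15/15 to the (4036, 866, 865) partition.
    """
    if n < 3:
        raise ValueError("need at least 3 points to split")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("split ratios must sum to 1")
    r_train, r_val, _ = ratios
    n_train = int(np.floor(r_train * n))
    n_val = int(np.ceil(r_val * n))
    n_test = n - n_train - n_val
    spec = SplitSpec(n_train, n_val, n_test)
    if min(spec) < 0:
        raise ValueError(f"split ratios {ratios} give a negative block for n={n}")
    return spec


def make_windows(series: MultivariateSeries, target_channel: str,
                 covariate_channels: Sequence[str], lookback: int,
                 horizon: int) -> list[WindowSample]:
    """Slice a series into strictly chronological (history, future) samples.

    Sample *i* takes positions ``[i, i+lookback)`` as history and
    ``[i+lookback, i+lookback+horizon)`` as the future targets, yielding
    ``n - lookback - horizon + 1`` samples.
    """
    if lookback < 1 or horizon < 1:
        raise ValueError("lookback and horizon must be >= 1")
    n = len(series)
    if n < lookback + horizon:
        raise ValueError(
            f"series length {n} is shorter than lookback+horizon={lookback + horizon}")
    target = series.channel(target_channel)
    cov = (series.values[list(covariate_channels)].to_numpy()
           if covariate_channels else np.empty((n, 0)))
    samples = []
    for i in range(n - lookback - horizon + 1):
        samples.append(WindowSample(
            history_targets=target[i:i + lookback],
            history_covariates=cov[i:i + lookback],
            future_targets=target[i + lookback:i + lookback + horizon],
        ))
    return samples


def windows_to_arrays(samples: Sequence[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack window samples into the flat (X, y) layout the estimators accept.

    X rows are ``[history_targets (T0) | history_covariates flattened (T0*d)]``;
    y rows are the future targets of length H.
    """
    X = np.stack([np.concatenate([s.history_targets,
                                  s.history_covariates.ravel()])
                  for s in samples])
    y = np.stack([s.future_targets for s in samples])
    return X, y
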
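"""End-to-end workflow: preprocess -> select features -> (optimize) -> train
-> evaluate -> forecast, with seeded reproducibility and JSON artifacts.

Every stage logs its parameters, writes its artifact under the output
directory, and aborts with the stage name on failure.  A manifest records
the resolved configuration and seed so a rerun reproduces identical output.
"""

from __future__ import annotations

import contextlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .series import (MultivariateSeries, read_series, fill_missing_linear,
                     fit_apply_minmax, chronological_split, make_windows,
                     windows_to_arrays, ScalingStats, SplitSpec)
from .synthetic import SimConfig, generate
from .features import lag_supervise, GradientBoostingFeatureSelector
from .nhits import NHiTSRegressor
from .gaussian import (NHiTSGaussianForecaster, NHiTSQuantileForecaster,
                       ResidualIntervalForecaster, IntervalForecast)
from .metrics import point_metrics, interval_metrics, IntervalMetricsConfig
from .smpso import SMPSO, NHiTSGObjective, select_final, default_search_space

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "forecast"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@contextlib.contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done", name)


@dataclass
class PipelineConfig:
    """Declarative description of one forecasting run.

    Either ``input_csv`` or ``simulate`` (synthetic-generator settings) must
    be given.  ``covariate_channels=None`` lets the gradient-boosting
    selector choose them; ``model`` holds estimator keyword overrides
    (lookback, mlp_units, ...).
    """

    input_csv: str | None = None
    simulate: dict | None = None
    timestamp_column: str = "timestamp"
    target_channel: str = "soil_temperature"
    covariate_channels: list[str] | None = None
    horizons: tuple = (1, 3, 6)
    split_ratios: tuple = (0.70, 0.15, 0.15)
    interval_method: str = "gaussian"
    level: float = 0.90
    model: dict = field(default_factory=dict)
    feature_selection: bool = True
    fs_estimator: str = "lightgbm"
    optimize: bool = False
    optimizer: dict = field(default_factory=dict)
    mu_threshold: float = 0.80
    eta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.input_csv is None and self.simulate is None:
            raise ValueError("config needs either input_csv or simulate")
        if any(int(h) < 1 for h in self.horizons):
            raise ValueError("horizons must be positive integers")
        if self.interval_method not in ("gaussian", "quantile", "error_fit",
                                        "bootstrap"):
            raise ValueError(f"unknown interval_method {self.interval_method!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["horizons"] = [int(h) for h in self.horizons]
        d["split_ratios"] = [float(r) for r in self.split_ratios]
        return d


def _model_for(config: PipelineConfig, hyper: dict, seed: int):
    """Instantiate the forecaster named by config.interval_method."""
    kwargs = dict(hyper)
    kwargs["random_state"] = seed
    if config.interval_method == "gaussian":
        return NHiTSGaussianForecaster(level=config.level, **kwargs)
    if config.interval_method == "quantile":
        return NHiTSQuantileForecaster(level=config.level, **kwargs)
    base = NHiTSRegressor(**kwargs)
    return ResidualIntervalForecaster(base_estimator=base,
                                      method=config.interval_method,
                                      level=config.level, random_state=seed)


def forecast(model, scaled_series: MultivariateSeries, stats: ScalingStats,
             target_channel: str, covariate_channels, horizon: int,
             level: float) -> pd.DataFrame:
    """Interval forecast from the latest lookback window, in original units.

    Rows carry future timestamps at the series cadence; columns are
    timestamp, median, lower, upper, level.
    """
    T0 = model.base_estimator_.lookback if hasattr(model, "base_estimator_") \
        else model.lookback
    n = len(scaled_series)
    if n < T0:
        raise ValueError(f"series shorter than model lookback {T0}")
    window = scaled_series.iloc_slice(n - T0, n)
    target = window.channel(target_channel)
    cov = (window.values[list(covariate_channels)].to_numpy()
           if covariate_channels else np.empty((T0, 0)))
    X = np.concatenate([target, cov.ravel()])[None, :]
    interval: IntervalForecast = model.predict_interval(X)
    step = pd.Timedelta(minutes=scaled_series.interval_minutes)
    future_ts = [scaled_series.timestamps[-1] + (h + 1) * step
                 for h in range(horizon)]
    A, xmin = stats.range(target_channel), stats.xmin[target_channel]
    inv = lambda v: np.asarray(v).ravel() * A + xmin  # noqa: E731
    return pd.DataFrame({
        "timestamp": future_ts,
        "median": inv(interval.median)[:horizon],
        "lower": inv(interval.lower)[:horizon],
        "upper": inv(interval.upper)[:horizon],
        "level": level,
    })


def _evaluate_on_test(model, test_series, config, stats, horizon):
    """Pooled point + interval metrics on the test partition, original units."""
    T0 = model.base_estimator_.lookback if hasattr(model, "base_estimator_") \
        else model.lookback
    Xt, yt = windows_to_arrays(make_windows(
        test_series, config.target_channel,
        config.covariate_channels or [], T0, horizon))
    interval = model.predict_interval(Xt)
    A = stats.range(config.target_channel)
    xmin = stats.xmin[config.target_channel]
    med = interval.median * A + xmin
    lo = interval.lower * A + xmin
    up = interval.upper * A + xmin
    obs = yt * A + xmin
    pm = point_metrics(med, obs)
    im = interval_metrics(obs, lo, up,
                          IntervalMetricsConfig(A=A,
                                                mu_threshold=config.mu_threshold,
                                                eta=config.eta))
    per_step = {}
    for j in range(horizon):
        im_j = interval_metrics(obs[:, j], lo[:, j], up[:, j],
                                IntervalMetricsConfig(A=A,
                                                      mu_threshold=config.mu_threshold,
                                                      eta=config.eta))
        per_step[f"step_{j + 1}"] = {**point_metrics(med[:, j], obs[:, j]).as_dict(),
                                     **im_j.as_dict()}
    return {**pm.as_dict(), **im.as_dict(), "per_step": per_step}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full workflow; returns a results dict and writes artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"horizons": {}}
    seed = int(config.seed)

    with _stage("load"):
        if config.simulate is not None:
            sim = SimConfig.from_dict({**config.simulate,
                                       "seed": config.simulate.get("seed", seed)})
            series = generate(sim)
            series.to_csv(outdir / "series.csv")
            sim.to_json(outdir / "sim_config.json")
        else:
            series = read_series(config.input_csv,
                                 timestamp_column=config.timestamp_column)
        missing = [c for c in ([config.target_channel]
                               + (config.covariate_channels or []))
                   if c not in series.channel_names]
        if missing:
            raise ValueError(f"channels not in series: {missing}")

    with _stage("preprocess"):
        series = fill_missing_linear(series)
        split = chronological_split(len(series), config.split_ratios)
        scaled, stats = fit_apply_minmax(series, split.n_train)
        stats.to_json(outdir / "scaling.json")
        results["split"] = {"n_train": split.n_train, "n_val": split.n_val,
                            "n_test": split.n_test}

    with _stage("select_features"):
        if config.covariate_channels is None and config.feature_selection:
            train_part = scaled.iloc_slice(0, split.n_train)
            feats, target = lag_supervise(train_part, config.target_channel,
                                          lag=1)
            selector = GradientBoostingFeatureSelector(
                estimator=config.fs_estimator, random_state=seed)
            selector.fit(feats, target)
            chosen = [f.rsplit("_lag", 1)[0] for f in selector.selected_features_]
            config.covariate_channels = [c for c in chosen
                                         if c != config.target_channel]
            with open(outdir / "features.json", "w") as fh:
                json.dump(selector.report(), fh, indent=2)
            results["selected_covariates"] = config.covariate_channels
        elif config.covariate_channels is None:
            config.covariate_channels = [c for c in series.channel_names
                                         if c != config.target_channel]

    hyper = dict(config.model)
    with _stage("optimize"):
        if config.optimize:
            opt = dict(config.optimizer)
            h_max = max(int(h) for h in config.horizons)
            objective = NHiTSGObjective(
                scaled, config.target_channel, config.covariate_channels,
                split, h_max, level=config.level,
                n_stacks=opt.get("n_stacks", hyper.get("n_stacks", 3)),
                max_epochs=opt.get("eval_max_epochs", 150),
                patience=opt.get("eval_patience", 50),
                mu_threshold=config.mu_threshold, eta=config.eta, seed=seed)
            optimizer = SMPSO(default_search_space(),
                              swarm_size=opt.get("swarm_size", 20),
                              iterations=opt.get("iterations", 25),
                              archive_capacity=opt.get("archive_capacity", 50),
                              seed=seed)
            archive = optimizer.optimize(objective)
            chosen = select_final(archive)
            assignment = chosen.payload["assignment"]
            hyper.update({
                "lookback": assignment["lookback"],
                "n_blocks": assignment["n_blocks"],
                "mlp_units": assignment["mlp_units"],
                "pool_kernel_sizes": assignment["n_pool_kernel_size"],
                "downsample_factors": assignment["n_freq_downsample"],
            })
            with open(outdir / "pareto_archive.json", "w") as fh:
                json.dump([{"position": list(e.position),
                            "objectives": list(e.objectives),
                            "assignment": e.payload.get("assignment")}
                           for e in archive.entries], fh, indent=2)
            with open(outdir / "selected_config.json", "w") as fh:
                json.dump(assignment, fh, indent=2)
            results["optimized_hyperparameters"] = assignment

    train_part = scaled.iloc_slice(0, split.n_train)
    val_part = scaled.iloc_slice(split.n_train, split.n_train + split.n_val)
    test_part = scaled.iloc_slice(split.n_train + split.n_val, len(scaled))

    for h_idx, horizon in enumerate(int(h) for h in config.horizons):
        with _stage(f"train_h{horizon}"):
            model = _model_for(config, hyper, seed + 101 + h_idx)
            T0 = (model.base_estimator.lookback
                  if isinstance(model, ResidualIntervalForecaster)
                  else model.lookback)
            X, y = windows_to_arrays(make_windows(
                train_part, config.target_channel, config.covariate_channels,
                T0, horizon))
            Xv, yv = windows_to_arrays(make_windows(
                val_part, config.target_channel, config.covariate_channels,
                T0, horizon))
            if isinstance(model, ResidualIntervalForecaster):
                model.fit(X, y, X_cal=Xv, y_cal=yv)
            else:
                model.fit(X, y, X_val=Xv, y_val=yv)
            if hasattr(model, "save"):
                model.save(str(outdir / f"model_h{horizon}"), scaling=stats)

        with _stage(f"evaluate_h{horizon}"):
            report = _evaluate_on_test(model, test_part, config, stats, horizon)
            with open(outdir / f"metrics_h{horizon}.json", "w") as fh:
                json.dump(report, fh, indent=2)
            results["horizons"][horizon] = report

        with _stage(f"predict_h{horizon}"):
            frame = forecast(model, scaled, stats, config.target_channel,
                             config.covariate_channels, horizon, config.level)
            frame.to_csv(outdir / f"forecast_h{horizon}.csv", index=False)

    with _stage("manifest"):
        import soilcast
        manifest = {"soilcast_version": soilcast.__version__,
                    "seed": seed, "config": config.to_dict()}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
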
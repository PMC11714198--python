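"""Synthetic greenhouse sensor-log generator with a closed-form forecast oracle.

Real greenhouse microclimate records show diurnal periodicity, lagged
cross-channel coupling (soil temperature follows air temperature with a
delay of an hour or two, buffered by the soil's thermal mass), strongly
autocorrelated sensor noise, and occasional missing records from network
dropouts.  The generator reproduces exactly those features with the minimal
structure that still admits closed-form conditional forecast distributions:

    channel_c(t) = mean_c + amp_c * sin(2*pi*t/steps_per_day + phase_c) + e_c(t)
    e_c(t)       = rho_c * e_c(t-1) + noise_sd_c * w(t),     w ~ N(0, 1)

and the target (soil temperature) additionally receives
``beta * (air_temperature(t - lag) - mean_air)``.  Because every stochastic
term is AR(1), the conditional distribution of the target h steps ahead
given the observed history is Gaussian with known mean and standard
deviation — the oracle used by the calibration and coverage tests.

Each channel draws from its own RNG stream keyed by (seed, channel name),
so adding a channel never perturbs the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import MultivariateSeries
from .gaussian import GaussianForecast

__all__ = ["ChannelSpec", "SimConfig", "generate", "true_forecast_distribution",
           "default_channels"]


@dataclass
class ChannelSpec:
    """Sinusoid-plus-AR(1) parameters of one sensor channel (channel units)."""

    mean: float
    amplitude: float = 0.0
    phase: float = 0.0
    ar1_rho: float = 0.8
    noise_sd: float = 0.1

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# Afternoon peak (~14:00) for air temperature at a 20-minute cadence;
# humidity in antiphase; soil damped and mostly driven through the coupling.
_AIR_PHASE = -2.1


def default_channels() -> dict[str, ChannelSpec]:
    """The emulated seven-channel greenhouse sensor suite."""
    return {
        "soil_temperature": ChannelSpec(25.0, 1.0, _AIR_PHASE - 0.5, 0.85, 0.12),
        "air_temperature": ChannelSpec(24.0, 6.0, _AIR_PHASE, 0.80, 0.25),
        "air_humidity": ChannelSpec(70.0, 12.0, _AIR_PHASE + np.pi, 0.80, 1.5),
        "soil_moisture": ChannelSpec(42.0, 1.5, _AIR_PHASE - 0.8, 0.90, 0.4),
        "light": ChannelSpec(350.0, 330.0, _AIR_PHASE, 0.70, 25.0),
        "soil_conductivity": ChannelSpec(310.0, 4.0, _AIR_PHASE - 0.8, 0.90, 1.5),
        "carbon_dioxide": ChannelSpec(460.0, 40.0, _AIR_PHASE + np.pi, 0.85, 8.0),
    }


@dataclass
class SimConfig:
    """Configuration of one synthetic greenhouse record.

    Defaults emulate the scale of a spring greenhouse deployment: ~80 days
    at a 20-minute cadence (5760 points), soil temperature coupled to air
    temperature with a 2-hour (6-step) lag, and a small fraction of missing
    records.
    """

    n_days: int = 80
    interval_minutes: float = 20.0
    channels: dict[str, ChannelSpec] = field(default_factory=default_channels)
    coupling_beta: float = 0.35
    coupling_lag: int = 6
    target_channel: str = "soil_temperature"
    source_channel: str = "air_temperature"
    n_noise_channels: int = 0
    noise_channel_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    start: str = "2024-02-14 00:00"

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.coupling_lag < 0:
            raise ValueError("coupling_lag must be >= 0")

    @property
    def steps_per_day(self) -> int:
        return int(round(1440.0 / self.interval_minutes))

    @property
    def n_points(self) -> int:
        return self.n_days * self.steps_per_day

    def all_channels(self) -> dict[str, ChannelSpec]:
        out = dict(self.channels)
        for i in range(self.n_noise_channels):
            out[f"noise_{i + 1}"] = ChannelSpec(
                mean=0.0, amplitude=0.0, ar1_rho=0.8,
                noise_sd=self.noise_channel_sd)
        return out

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "channels" in d:
            d["channels"] = {k: ChannelSpec(**v) for k, v in d["channels"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _channel_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """AR(1) with innovation sd *sd*, started from its stationary law."""
    e = np.empty(n)
    if sd == 0.0:
        e[:] = 0.0
        return e
    stat_sd = sd / np.sqrt(1.0 - rho**2) if rho > 0 else sd
    e[0] = rng.normal(0.0, stat_sd)
    w = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + w[t - 1]
    return e


def _sinusoid(spec: ChannelSpec, t: np.ndarray, spd: int) -> np.ndarray:
    return spec.mean + spec.amplitude * np.sin(2 * np.pi * t / spd + spec.phase)


def generate(config: SimConfig) -> MultivariateSeries:
    """Generate a greenhouse-like multichannel record, reproducible from seed."""
    n = config.n_points
    spd = config.steps_per_day
    lag = config.coupling_lag
    channels = config.all_channels()

    data: dict[str, np.ndarray] = {}
    for name, spec in channels.items():
        rng = _channel_rng(config.seed, name)
        if name == config.source_channel and config.coupling_beta != 0.0:
            # extend backwards by `lag` steps so the coupling is defined at t=0
            t = np.arange(-lag, n, dtype=float)
            ext = _sinusoid(spec, t, spd) + _ar1(rng, n + lag, spec.ar1_rho,
                                                 spec.noise_sd)
            data[name] = ext[lag:]
            data["__source_ext"] = ext
        else:
            t = np.arange(n, dtype=float)
            data[name] = _sinusoid(spec, t, spd) + _ar1(rng, n, spec.ar1_rho,
                                                        spec.noise_sd)

    if config.coupling_beta != 0.0:
        src_mean = channels[config.source_channel].mean
        ext = data.pop("__source_ext")
        # air deviation `lag` steps earlier, i.e. ext index t
        data[config.target_channel] = (
            data[config.target_channel]
            + config.coupling_beta * (ext[:n] - src_mean))
    data.pop("__source_ext", None)

    values = pd.DataFrame({name: data[name] for name in channels})

    if config.missing_rate > 0.0:
        rng = _channel_rng(config.seed, "__missing__")
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)

    timestamps = pd.date_range(config.start, periods=n,
                               freq=pd.Timedelta(minutes=config.interval_minutes))
    return MultivariateSeries(timestamps=pd.DatetimeIndex(timestamps),
                              values=values,
                              interval_minutes=config.interval_minutes)


def true_forecast_distribution(config: SimConfig, series: MultivariateSeries,
                               horizon: int,
                               t0: int | None = None) -> GaussianForecast:
    """Analytic conditional forecast distribution of the target channel.

    Given the observed history up to index *t0* (default: the last point of
    *series*, which must be a record produced by :func:`generate` with this
    config, gap-free), returns the exact Gaussian conditional mean and
    standard deviation of the target at ``t0+1 .. t0+horizon``.

    Requires ``coupling_lag >= horizon`` when ``coupling_beta != 0`` (so the
    coupled air value for every forecast step is already observed) and a
    history reaching back at least ``coupling_lag`` steps.
    """
    beta, lag = config.coupling_beta, config.coupling_lag
    if beta != 0.0 and lag < horizon:
        raise ValueError(
            f"conditional distribution undefined: coupling_lag={lag} < "
            f"horizon={horizon} with nonzero coupling_beta")
    t0 = len(series) - 1 if t0 is None else t0
    if beta != 0.0 and t0 < lag:
        raise ValueError("history must reach back at least coupling_lag steps")

    spec = config.channels[config.target_channel]
    spd = config.steps_per_day
    target_obs = series.channel(config.target_channel)
    source_obs = (series.channel(config.source_channel)
                  if beta != 0.0 else None)
    src_mean = (config.channels[config.source_channel].mean
                if beta != 0.0 else 0.0)

    def det(t: int) -> float:
        base = float(_sinusoid(spec, np.array([float(t)]), spd)[0])
        if beta != 0.0:
            base += beta * (float(source_obs[t - lag]) - src_mean)
        return base

    resid = float(target_obs[t0]) - det(t0)
    rho, sd = spec.ar1_rho, spec.noise_sd
    mu = np.empty(horizon)
    sigma = np.empty(horizon)
    for h in range(1, horizon + 1):
        mu[h - 1] = det(t0 + h) + rho**h * resid
        sigma[h - 1] = sd * np.sqrt(sum(rho ** (2 * k) for k in range(h)))
    return GaussianForecast(mu=mu, sigma=sigma)
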
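"""Speed-constrained multi-objective particle swarm optimization (SMPSO).

Searches the integer hyperparameter space of the Gaussian N-HiTS forecaster
for configurations that jointly minimize the point-forecast MAE and the
coverage-width criterion CWC of the 90% interval on the validation
partition.  SMPSO extends multi-objective PSO with a constriction factor
and per-dimension velocity bounds (half the variable range) so particles
cannot overshoot the feasible box, an external bounded archive of mutually
nondominated solutions pruned by crowding distance, leader selection by
binary tournament on crowding distance, and polynomial mutation of a
fraction of the swarm each iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SearchSpace", "ParetoArchive", "SMPSO", "dominates", "decode",
           "select_final", "default_search_space"]

log = logging.getLogger(__name__)

SENTINEL = (np.inf, np.inf)  # failed evaluation; never archived


@dataclass(frozen=True)
class SearchSpace:
    """Named integer box constraints, one (lower, upper) pair per dimension."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    @classmethod
    def from_dict(cls, bounds: dict[str, tuple[int, int]]) -> "SearchSpace":
        names = tuple(bounds)
        lo = np.array([bounds[n][0] for n in names], dtype=float)
        hi = np.array([bounds[n][1] for n in names], dtype=float)
        if np.any(lo > hi):
            raise ValueError("lower bound exceeds upper bound")
        return cls(names=names, lower=lo, upper=hi)

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def delta(self) -> np.ndarray:
        """Velocity bound per dimension: half the variable range."""
        return (self.upper - self.lower) / 2.0


def default_search_space() -> SearchSpace:
    """The forecaster's hyperparameter search box (all integer-valued)."""
    return SearchSpace.from_dict({
        "n_blocks": (1, 5),
        "mlp_units": (100, 500),
        "n_pool_kernel_size": (2, 5),
        "n_freq_downsample": (1, 5),
        "lookback": (5, 24),
    })


def decode(position: np.ndarray, space: SearchSpace) -> dict[str, int]:
    """Round each coordinate half-up to an integer and clamp into bounds."""
    out = {}
    for i, name in enumerate(space.names):
        v = int(np.floor(position[i] + 0.5))
        out[name] = int(np.clip(v, space.lower[i], space.upper[i]))
    return out


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Pareto dominance for minimization: a <= b everywhere, < somewhere."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return bool(np.all(a <= b) and np.any(a < b))


@dataclass
class ArchiveEntry:
    position: np.ndarray
    objectives: tuple[float, float]
    payload: dict = field(default_factory=dict)


class ParetoArchive:
    """Bounded external archive of mutually nondominated solutions."""

    def __init__(self, capacity: int = 50):
        self.capacity = capacity
        self.entries: list[ArchiveEntry] = []

    def __len__(self) -> int:
        return len(self.entries)

    def objectives(self) -> np.ndarray:
        return np.array([e.objectives for e in self.entries], dtype=float)

    def add(self, position, objectives, payload=None) -> bool:
        """Insert a candidate unless dominated; evict dominated entries;
        prune the most crowded entry when over capacity."""
        objectives = tuple(float(v) for v in objectives)
        if not all(np.isfinite(objectives)):
            return False
        for e in self.entries:
            if dominates(e.objectives, objectives) or e.objectives == objectives:
                return False
        self.entries = [e for e in self.entries
                        if not dominates(objectives, e.objectives)]
        self.entries.append(ArchiveEntry(np.array(position, dtype=float),
                                         objectives, payload or {}))
        if len(self.entries) > self.capacity:
            cd = self.crowding_distances()
            self.entries.pop(int(np.argmin(cd)))
        return True

    def crowding_distances(self) -> np.ndarray:
        """NSGA-II crowding distance over the archive's objective vectors;
        boundary entries get +inf and are never pruned."""
        objs = self.objectives()
        n, m = objs.shape
        if n <= 2:
            return np.full(n, np.inf)
        cd = np.zeros(n)
        for j in range(m):
            order = np.argsort(objs[:, j], kind="stable")
            cd[order[0]] = cd[order[-1]] = np.inf
            span = objs[order[-1], j] - objs[order[0], j]
            if span == 0:
                continue
            for k in range(1, n - 1):
                cd[order[k]] += (objs[order[k + 1], j]
                                 - objs[order[k - 1], j]) / span
        return cd

    def is_mutually_nondominated(self) -> bool:
        objs = self.objectives()
        for i in range(len(objs)):
            for j in range(len(objs)):
                if i != j and dominates(objs[i], objs[j]):
                    return False
        return True


def constriction_factor(c1: float, c2: float) -> float:
    """chi = 2 / |2 - phi - sqrt(phi^2 - 4 phi)| for phi = c1 + c2 > 4, else 1.

    The magnitude of the denominator is used, as in the reference SMPSO
    implementations, so the factor always damps rather than reflects.
    """
    phi = c1 + c2
    if phi <= 4.0:
        return 1.0
    return 2.0 / abs(2.0 - phi - np.sqrt(phi**2 - 4.0 * phi))


def velocity_position_update(position, velocity, pbest, leader,
                             space: SearchSpace, rng: np.random.Generator,
                             w: float = 0.1):
    """One SMPSO move: constricted velocity update, velocity clamping to
    +/- delta, position clamp with velocity sign reversal at the bounds."""
    c1 = rng.uniform(1.5, 2.5)
    c2 = rng.uniform(1.5, 2.5)
    r1 = rng.uniform(0.0, 1.0, size=space.ndim)
    r2 = rng.uniform(0.0, 1.0, size=space.ndim)
    chi = constriction_factor(c1, c2)
    v = chi * (w * velocity + c1 * r1 * (pbest - position)
               + c2 * r2 * (leader - position))
    delta = space.delta
    v = np.clip(v, -delta, delta)
    x = position + v
    below, above = x < space.lower, x > space.upper
    v = np.where(below | above, -v, v)
    x = np.clip(x, space.lower, space.upper)
    return x, v


def polynomial_mutation(position, space: SearchSpace,
                        rng: np.random.Generator, eta: float = 20.0):
    """Polynomial mutation, probability 1/ndim per dimension."""
    x = position.copy()
    p = 1.0 / space.ndim
    for i in range(space.ndim):
        if rng.random() >= p:
            continue
        lo, hi = space.lower[i], space.upper[i]
        if hi == lo:
            continue
        u = rng.random()
        d1 = (x[i] - lo) / (hi - lo)
        d2 = (hi - x[i]) / (hi - lo)
        if u < 0.5:
            dq = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1)) ** (1 / (eta + 1)) - 1
        else:
            dq = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1)) ** (1 / (eta + 1))
        x[i] = np.clip(x[i] + dq * (hi - lo), lo, hi)
    return x


class SMPSO:
    """The swarm loop: initialize, evaluate, archive, iterate.

    ``evaluate_fn`` maps a decoded integer assignment (dict) to a pair of
    objectives to minimize; evaluations are memoized by the decoded key.
    A raised exception or non-finite objectives mark the candidate as failed:
    it is logged, skipped for the archive, and never becomes a personal best.
    """

    def __init__(self, space: SearchSpace | None = None, swarm_size: int = 20,
                 iterations: int = 25, archive_capacity: int = 50,
                 mutation_fraction: float = 0.15, w: float = 0.1,
                 seed: int = 0):
        self.space = space or default_search_space()
        self.swarm_size = swarm_size
        self.iterations = iterations
        self.archive_capacity = archive_capacity
        self.mutation_fraction = mutation_fraction
        self.w = w
        self.seed = seed

    def _evaluate(self, position, evaluate_fn, cache) -> tuple[float, float]:
        assignment = decode(position, self.space)
        key = tuple(sorted(assignment.items()))
        if key in cache:
            return cache[key]
        try:
            objectives = tuple(float(v) for v in evaluate_fn(assignment))
        except Exception as exc:  # noqa: BLE001 - candidate failure is data
            log.warning("candidate %s failed: %s", assignment, exc)
            objectives = SENTINEL
        if not all(np.isfinite(objectives)):
            objectives = SENTINEL
        cache[key] = objectives
        return objectives

    def _select_leader(self, archive: ParetoArchive,
                       rng: np.random.Generator) -> np.ndarray:
        cd = archive.crowding_distances()
        i, j = rng.integers(0, len(archive), size=2)
        winner = i if cd[i] >= cd[j] else j
        return archive.entries[winner].position

    def optimize(self, evaluate_fn: Callable[[dict], Sequence[float]]
                 ) -> ParetoArchive:
        rng = np.random.default_rng(self.seed)
        space = self.space
        cache: dict = {}
        archive = ParetoArchive(self.archive_capacity)

        positions = rng.uniform(space.lower, space.upper,
                                size=(self.swarm_size, space.ndim))
        velocities = np.zeros_like(positions)
        pbest = positions.copy()
        pbest_obj = []
        for i in range(self.swarm_size):
            obj = self._evaluate(positions[i], evaluate_fn, cache)
            pbest_obj.append(obj)
            archive.add(positions[i], obj,
                        {"assignment": decode(positions[i], space)})
        if len(archive) == 0:
            raise RuntimeError("no candidate evaluated successfully")
        self.archive_history_ = [archive.objectives().copy()]

        n_mutate = int(round(self.mutation_fraction * self.swarm_size))
        for _ in range(self.iterations):
            for i in range(self.swarm_size):
                leader = self._select_leader(archive, rng)
                positions[i], velocities[i] = velocity_position_update(
                    positions[i], velocities[i], pbest[i], leader, space,
                    rng, w=self.w)
            if n_mutate:
                chosen = rng.choice(self.swarm_size, size=n_mutate,
                                    replace=False)
                for i in chosen:
                    positions[i] = polynomial_mutation(positions[i], space, rng)
            for i in range(self.swarm_size):
                obj = self._evaluate(positions[i], evaluate_fn, cache)
                archive.add(positions[i], obj,
                            {"assignment": decode(positions[i], space)})
                if not all(np.isfinite(obj)):
                    continue
                if (not all(np.isfinite(pbest_obj[i]))
                        or dominates(obj, pbest_obj[i])
                        or (not dominates(pbest_obj[i], obj)
                            and rng.random() < 0.5)):
                    pbest[i] = positions[i].copy()
                    pbest_obj[i] = obj
            self.archive_history_.append(archive.objectives().copy())
        return archive


class NHiTSGObjective:
    """Evaluate one hyperparameter assignment of the Gaussian forecaster.

    Builds lookback windows per candidate (the lookback itself is searched),
    trains the forecaster on the training partition with early stopping on
    the validation partition, and returns the validation-set
    (MAE of the interval median, CWC of the level-confidence interval), both
    in scaled target units (normalization range A = 1 after min-max scaling).
    Results are memoized upstream by decoded integer key; training failures
    propagate and are turned into sentinel objectives by the optimizer.
    """

    def __init__(self, series, target_channel, covariate_channels, split,
                 horizon, level=0.90, n_stacks=3, max_epochs=150, patience=50,
                 batch_size=32, learning_rate=1e-3, n_samples=500,
                 mu_threshold=0.80, eta=1.0, seed=0):
        self.series = series            # scaled, gap-free
        self.target_channel = target_channel
        self.covariate_channels = list(covariate_channels)
        self.split = split
        self.horizon = horizon
        self.level = level
        self.n_stacks = n_stacks
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.n_samples = n_samples
        self.mu_threshold = mu_threshold
        self.eta = eta
        self.seed = seed

    def __call__(self, assignment: dict) -> tuple[float, float]:
        from .series import make_windows, windows_to_arrays
        from .gaussian import NHiTSGaussianForecaster
        from .metrics import interval_metrics, IntervalMetricsConfig

        T0 = assignment["lookback"]
        n_train, n_val = self.split.n_train, self.split.n_val
        train = self.series.iloc_slice(0, n_train)
        val = self.series.iloc_slice(n_train, n_train + n_val)
        X, y = windows_to_arrays(make_windows(
            train, self.target_channel, self.covariate_channels,
            T0, self.horizon))
        Xv, yv = windows_to_arrays(make_windows(
            val, self.target_channel, self.covariate_channels,
            T0, self.horizon))
        model = NHiTSGaussianForecaster(
            lookback=T0, n_stacks=self.n_stacks,
            n_blocks=assignment["n_blocks"],
            mlp_units=assignment["mlp_units"],
            pool_kernel_sizes=assignment["n_pool_kernel_size"],
            downsample_factors=assignment["n_freq_downsample"],
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
            random_state=self.seed, level=self.level,
            n_samples=self.n_samples)
        model.fit(X, y, X_val=Xv, y_val=yv)
        interval = model.predict_interval(Xv)
        mae = float(np.mean(np.abs(interval.median - yv)))
        im = interval_metrics(
            yv, interval.lower, interval.upper,
            IntervalMetricsConfig(A=1.0, mu_threshold=self.mu_threshold,
                                  eta=self.eta))
        return mae, im.cwc


def select_final(archive: ParetoArchive) -> ArchiveEntry:
    """Knee-point rule: min-max normalize the archived objectives and return
    the entry closest (Euclidean) to the ideal (0, 0); ties -> lower CWC."""
    if len(archive) == 0:
        raise ValueError("archive is empty")
    objs = archive.objectives()
    lo = objs.min(axis=0)
    span = np.where(objs.max(axis=0) > lo, objs.max(axis=0) - lo, 1.0)
    norm = (objs - lo) / span
    dist = np.sqrt((norm**2).sum(axis=1))
    best = np.flatnonzero(np.isclose(dist, dist.min()))
    if len(best) > 1:
        best = best[np.argsort(objs[best, 1], kind="stable")]
    return archive.entries[int(best[0])]
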
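"""N-HiTS: neural hierarchical-interpolation networks for direct multi-step
forecasting.

The architecture is a chain of fully connected blocks grouped into stacks.
Each block sees the current residual of the lookback window after
max-pooling with its stack's kernel (multi-rate sampling), concatenated
with the flattened covariate history.  A two-hidden-layer ReLU MLP maps
this to (i) a backcast of the full lookback window, subtracted from the
next block's input, and (ii) a coarse set of forecast "knots" — one set
per output channel — which are up-sampled to the full horizon by linear
interpolation (hierarchical interpolation).  The model forecast is the sum
of all block forecasts; all horizon steps are predicted jointly (direct,
non-recursive multi-step forecasting).

Training uses Adam with early stopping on a chronological validation tail:
when the validation loss has not improved for `patience` epochs the run
stops and the best-validation parameters are restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import _autodiff as A
from ._autodiff import Tensor, Adam, backward

__all__ = ["NHiTSConfig", "NHiTSRegressor", "multirate_pool",
           "interpolation_matrix", "mae_loss", "train_network"]


def multirate_pool(window: np.ndarray, kernel: int) -> np.ndarray:
    """Non-overlapping max pooling with stride = kernel; ragged tail kept.

    Output length is ceil(len/kernel); the last pool may cover fewer than
    `kernel` elements.
    """
    if kernel < 1:
        raise ValueError("pooling kernel must be >= 1")
    x = np.asarray(window, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    out = A.maxpool1d(Tensor(x), kernel).data
    return out[0] if squeeze else out


def interpolation_matrix(n_knots: int, horizon: int) -> np.ndarray:
    """Linear-interpolation operator (n_knots x horizon).

    Knots sit at equally spaced positions across [0, horizon-1] with the
    endpoints pinned to the first/last knot; a single knot yields a constant
    forecast.  With n_knots == horizon the operator is the identity.
    """
    if n_knots < 1 or horizon < 1:
        raise ValueError("n_knots and horizon must be >= 1")
    if n_knots > horizon:
        raise ValueError("n_knots cannot exceed the horizon")
    M = np.zeros((n_knots, horizon))
    if n_knots == 1:
        M[0, :] = 1.0
        return M
    knot_pos = np.linspace(0.0, horizon - 1.0, n_knots)
    for h in range(horizon):
        j = int(np.searchsorted(knot_pos, h, side="right")) - 1
        j = min(max(j, 0), n_knots - 2)
        span = knot_pos[j + 1] - knot_pos[j]
        w = (h - knot_pos[j]) / span
        M[j, h] = 1.0 - w
        M[j + 1, h] = w
    return M


@dataclass
class NHiTSConfig:
    """Architecture and training settings of an N-HiTS forecaster.

    Per-stack settings (`n_blocks`, `pool_kernel_sizes`,
    `downsample_factors`) may be a single int, replicated across stacks,
    or a sequence of length `n_stacks`.
    """

    lookback: int = 12
    horizon: int = 6
    n_stacks: int = 3
    n_blocks: int | tuple = 1
    mlp_units: int = 128
    pool_kernel_sizes: int | tuple = (4, 2, 1)
    downsample_factors: int | tuple = (4, 2, 1)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0

    def per_stack(self, value) -> list[int]:
        if np.isscalar(value):
            return [int(value)] * self.n_stacks
        value = list(value)
        if len(value) != self.n_stacks:
            raise ValueError(
                f"per-stack setting {value} does not match n_stacks={self.n_stacks}")
        return [int(v) for v in value]


class _Block:
    """One MLP block: pooled input -> backcast + forecast knots."""

    def __init__(self, in_dim: int, mlp_units: int, lookback: int,
                 n_knots: int, out_channels: int, rng: np.random.Generator):
        def glorot(fan_in, fan_out, scale=1.0):
            lim = scale * np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-lim, lim, size=(fan_in, fan_out)))

        self.n_knots = n_knots
        self.W1 = glorot(in_dim, mlp_units)
        self.b1 = Tensor(np.zeros(mlp_units))
        self.W2 = glorot(mlp_units, mlp_units)
        self.b2 = Tensor(np.zeros(mlp_units))
        # heads start near zero so the residual chain begins close to identity
        self.Wback = glorot(mlp_units, lookback, scale=0.1)
        self.bback = Tensor(np.zeros(lookback))
        self.Wfore = glorot(mlp_units, n_knots * out_channels, scale=0.1)
        self.bfore = Tensor(np.zeros(n_knots * out_channels))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2,
                self.Wback, self.bback, self.Wfore, self.bfore]

    def forward(self, inp: Tensor) -> tuple[Tensor, Tensor]:
        h = A.relu(A.add(A.matmul(inp, self.W1), self.b1))
        h = A.relu(A.add(A.matmul(h, self.W2), self.b2))
        backcast = A.add(A.matmul(h, self.Wback), self.bback)
        knots = A.add(A.matmul(h, self.Wfore), self.bfore)
        return backcast, knots


class _NHiTSNet:
    """The full residual chain of stacks/blocks with hierarchical interpolation."""

    def __init__(self, config: NHiTSConfig, cov_width: int, out_channels: int):
        # cov_width: flattened covariate length appended to every block input
        cfg = config
        self.config = cfg
        self.cov_width = cov_width
        self.out_channels = out_channels
        rng = np.random.default_rng(cfg.seed)
        kernels = cfg.per_stack(cfg.pool_kernel_sizes)
        downs = cfg.per_stack(cfg.downsample_factors)
        blocks_per_stack = cfg.per_stack(cfg.n_blocks)

        self.blocks: list[_Block] = []
        self.block_kernels: list[int] = []
        self.block_interp: list[np.ndarray] = []
        for s in range(cfg.n_stacks):
            k = kernels[s]
            d = downs[s]
            if k < 1 or d < 1:
                raise ValueError("pool kernels and downsample factors must be >= 1")
            pooled_len = -(-cfg.lookback // k)
            n_knots = max(-(-cfg.horizon // d), 1)
            M = interpolation_matrix(n_knots, cfg.horizon)
            for _ in range(blocks_per_stack[s]):
                self.blocks.append(_Block(pooled_len + cov_width, cfg.mlp_units,
                                          cfg.lookback, n_knots, out_channels,
                                          rng))
                self.block_kernels.append(k)
                self.block_interp.append(M)

    def params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params())
        return out

    def forward(self, x: np.ndarray, z: np.ndarray | None
                ) -> tuple[list[Tensor], list[list[np.ndarray]]]:
        """Run the residual chain on history targets x (B, T0) and flattened
        covariates z (B, T0*d).

        Returns per-output-channel forecast Tensors of shape (B, H) and, for
        instrumentation, each block's per-channel forecast contribution.
        """
        cur = Tensor(x)
        zt = Tensor(z) if z is not None and z.size else None
        C = self.out_channels
        totals: list[Tensor | None] = [None] * C
        contributions: list[list[np.ndarray]] = []
        for block, kernel, M in zip(self.blocks, self.block_kernels,
                                    self.block_interp):
            pooled = A.maxpool1d(cur, kernel)
            inp = A.concat([pooled, zt], axis=1) if zt is not None else pooled
            backcast, knots = block.forward(inp)
            q = block.n_knots
            Mt = Tensor(M)
            per_channel = []
            for c in range(C):
                fc = A.matmul(A.col_slice(knots, c * q, (c + 1) * q), Mt)
                totals[c] = fc if totals[c] is None else A.add(totals[c], fc)
                per_channel.append(fc.data)
            contributions.append(per_channel)
            cur = A.sub(cur, backcast)
        return totals, contributions  # type: ignore[return-value]

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights):
            p.data = np.array(w, dtype=float)


def mae_loss(outputs: list[Tensor], y: np.ndarray) -> Tensor:
    """Mean absolute error of the single-channel forecast (point training loss)."""
    return A.mean(A.absval(A.sub(outputs[0], Tensor(y))))


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


def train_network(net: _NHiTSNet, loss_fn, X: np.ndarray, Z: np.ndarray | None,
                  y: np.ndarray, X_val: np.ndarray, Z_val: np.ndarray | None,
                  y_val: np.ndarray, *, learning_rate: float = 1e-3,
                  batch_size: int = 32, max_epochs: int = 500,
                  patience: int = 50, seed: int = 0) -> TrainHistory:
    """Minibatch Adam training with early stopping on validation loss.

    Stops once the validation loss has failed to improve for `patience`
    consecutive epochs and restores the best-validation weights.  Fully
    reproducible given the seed (shuffling is the only randomness here;
    weight init is seeded at network construction).
    """
    if len(X) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(seed)
    opt = Adam(net.params(), lr=learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_weights = net.get_weights()
    epochs_since_best = 0
    n = len(X)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            outs, _ = net.forward(X[idx], None if Z is None else Z[idx])
            loss = loss_fn(outs, y[idx])
            opt.zero_grad()
            backward(loss)
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.train_loss.append(epoch_loss / n)

        outs, _ = net.forward(X_val, Z_val)
        val = float(loss_fn(outs, y_val).data)
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_weights = net.get_weights()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= patience:
                break
    net.set_weights(best_weights)
    return history


class _BaseNHiTS(BaseEstimator):
    """Shared fit machinery of the N-HiTS estimators.

    X rows are ``[history_targets (lookback) | history_covariates flattened
    (lookback * d)]`` (the layout produced by
    :func:`soilcast.series.windows_to_arrays`); y rows are the future targets.
    """

    _out_channels = 1

    def __init__(self, lookback=12, n_stacks=3, n_blocks=1, mlp_units=128,
                 pool_kernel_sizes=(4, 2, 1), downsample_factors=(4, 2, 1),
                 learning_rate=1e-3, batch_size=32, max_epochs=500,
                 patience=50, validation_fraction=0.15, random_state=0):
        self.lookback = lookback
        self.n_stacks = n_stacks
        self.n_blocks = n_blocks
        self.mlp_units = mlp_units
        self.pool_kernel_sizes = pool_kernel_sizes
        self.downsample_factors = downsample_factors
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- subclass hooks -------------------------------------------------
    def _loss_fn(self):
        raise NotImplementedError

    # -------------------------------------------------------------------
    def _split_xz(self, X):
        T0 = self.lookback
        if X.shape[1] < T0 or (X.shape[1] - T0) % T0 != 0:
            raise ValueError(
                f"X has {X.shape[1]} columns; expected lookback ({T0}) target "
                "columns plus lookback*d flattened covariate columns")
        return X[:, :T0], X[:, T0:]

    def fit(self, X, y, X_val=None, y_val=None):
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self._y_was_1d = y.ndim == 1
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.n_features_in_ = X.shape[1]
        self.horizon_ = y.shape[1]
        Xt, Z = self._split_xz(X)
        self.cov_dim_ = Z.shape[1] // self.lookback

        if X_val is None:
            n_val = max(int(round(self.validation_fraction * len(X))), 1)
            if n_val >= len(X):
                raise ValueError("validation_fraction leaves no training data")
            Xt, Xt_val = Xt[:-n_val], Xt[-n_val:]
            Z, Z_val = Z[:-n_val], Z[-n_val:]
            y, y_val = y[:-n_val], y[-n_val:]
        else:
            X_val = check_array(X_val, dtype=np.float64)
            y_val = np.asarray(y_val, dtype=np.float64)
            if y_val.ndim == 1:
                y_val = y_val[:, None]
            Xt_val, Z_val = self._split_xz(X_val)

        seed = 0 if self.random_state is None else int(self.random_state)
        cfg = NHiTSConfig(
            lookback=self.lookback, horizon=self.horizon_,
            n_stacks=self.n_stacks, n_blocks=self.n_blocks,
            mlp_units=self.mlp_units,
            pool_kernel_sizes=self.pool_kernel_sizes,
            downsample_factors=self.downsample_factors,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, seed=seed)
        self.config_ = cfg
        self.net_ = _NHiTSNet(cfg, cov_width=self.cov_dim_ * self.lookback,
                              out_channels=self._out_channels)
        self.history_ = train_network(
            self.net_, self._loss_fn(), Xt, Z, y, Xt_val, Z_val, y_val,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, seed=seed)
        return self

    def _forward(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=np.float64)
        Xt, Z = self._split_xz(X)
        outs, contribs = self.net_.forward(Xt, Z if Z.size else None)
        return outs, contribs

    def forward_contributions(self, X):
        """Per-block forecast contributions (instrumentation; channel 0)."""
        outs, contribs = self._forward(X)
        return outs[0].data, [c[0] for c in contribs]

    # -- checkpointing ---------------------------------------------------
    def save(self, prefix: str, scaling=None) -> None:
        """Serialize config (+ optional ScalingStats) to JSON and weights to NPZ."""
        check_is_fitted(self, "net_")
        meta = {
            "class": type(self).__name__,
            "params": self.get_params(),
            "horizon": self.horizon_,
            "cov_dim": self.cov_dim_,
            "y_was_1d": self._y_was_1d,
        }
        if scaling is not None:
            meta["scaling"] = {"xmin": scaling.xmin, "xmax": scaling.xmax}
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=lambda o: list(o))
        np.savez(f"{prefix}.npz",
                 **{f"w{i}": w for i, w in enumerate(self.net_.get_weights())})


def load_forecaster(prefix: str):
    """Load an estimator saved with :meth:`_BaseNHiTS.save`.

    Returns ``(estimator, ScalingStats or None)``.
    """
    from .gaussian import NHiTSGaussianForecaster, NHiTSQuantileForecaster
    from .series import ScalingStats

    classes = {c.__name__: c for c in
               (NHiTSRegressor, NHiTSGaussianForecaster, NHiTSQuantileForecaster)}
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    params = meta["params"]
    for key in ("pool_kernel_sizes", "downsample_factors", "n_blocks"):
        if isinstance(params.get(key), list):
            params[key] = tuple(params[key])
    est = classes[meta["class"]](**params)
    est.horizon_ = meta["horizon"]
    est.cov_dim_ = meta["cov_dim"]
    est._y_was_1d = meta["y_was_1d"]
    est.n_features_in_ = est.lookback * (1 + est.cov_dim_)
    seed = 0 if est.random_state is None else int(est.random_state)
    cfg = NHiTSConfig(
        lookback=est.lookback, horizon=est.horizon_, n_stacks=est.n_stacks,
        n_blocks=est.n_blocks, mlp_units=est.mlp_units,
        pool_kernel_sizes=est.pool_kernel_sizes,
        downsample_factors=est.downsample_factors, seed=seed)
    est.config_ = cfg
    est.net_ = _NHiTSNet(cfg, cov_width=est.cov_dim_ * est.lookback,
                         out_channels=est._out_channels)
    with np.load(f"{prefix}.npz") as data:
        est.net_.set_weights([data[f"w{i}"] for i in range(len(data.files))])
    from .nhits import TrainHistory
    est.history_ = TrainHistory()
    scaling = None
    if "scaling" in meta:
        scaling = ScalingStats(xmin=meta["scaling"]["xmin"],
                               xmax=meta["scaling"]["xmax"])
    return est, scaling


class NHiTSRegressor(_BaseNHiTS, RegressorMixin):
    """Direct multi-step point forecaster trained with MAE loss."""

    _out_channels = 1

    def _loss_fn(self):
        return mae_loss

    def predict(self, X):
        outs, _ = self._forward(X)
        pred = outs[0].data
        return pred.ravel() if self._y_was_1d else pred
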
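import numpy as np
import pytest

from soilcast import (NHiTSRegressor, multirate_pool, interpolation_matrix,
                      SimConfig, ChannelSpec, generate, fit_apply_minmax,
                      make_windows, windows_to_arrays, load_forecaster)
from soilcast.nhits import NHiTSConfig, _NHiTSNet


def _relu(x):
    return np.maximum(x, 0.0)


class TestMultiratePool:
    def test_kernel_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(multirate_pool(x, 1), x)

    def test_pairwise_max(self):
        np.testing.assert_array_equal(multirate_pool([1, 5, 2, 4], 2), [5, 4])

    def test_ragged_tail_kept(self):
        np.testing.assert_array_equal(multirate_pool([1, 5, 2], 2), [5, 2])

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            multirate_pool([1.0, 2.0], 0)


class TestInterpolation:
    def test_full_rate_is_identity(self):
        np.testing.assert_array_equal(interpolation_matrix(6, 6), np.eye(6))

    def test_single_knot_constant(self):
        M = interpolation_matrix(1, 5)
        np.testing.assert_array_equal(np.array([2.5]) @ M, np.full(5, 2.5))

    def test_endpoints_pinned_and_linear_between(self):
        M = interpolation_matrix(2, 5)
        out = np.array([0.0, 4.0]) @ M
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0, 3.0, 4.0])

    def test_rows_sum_to_one(self):
        for q, h in [(2, 6), (3, 6), (4, 7), (1, 1)]:
            M = interpolation_matrix(q, h)
            np.testing.assert_allclose(M.sum(axis=0), np.ones(h))

    def test_more_knots_than_steps_rejected(self):
        with pytest.raises(ValueError):
            interpolation_matrix(3, 1)


def _tiny_net(**kw):
    cfg = NHiTSConfig(lookback=4, horizon=2, n_stacks=1, n_blocks=2,
                      mlp_units=3, pool_kernel_sizes=2, downsample_factors=2,
                      seed=0, **kw)
    return _NHiTSNet(cfg, cov_width=0, out_channels=1)


class TestForward:
    def test_zero_parameters_give_zero_output(self):
        net = _tiny_net()
        net.set_weights([np.zeros_like(w) for w in net.get_weights()])
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        outs, contribs = net.forward(x, None)
        np.testing.assert_array_equal(outs[0].data, np.zeros((1, 2)))
        for per_channel in contribs:
            np.testing.assert_array_equal(per_channel[0], np.zeros((1, 2)))

    def test_two_block_residual_chain_matches_hand_trace(self):
        # independent step-by-step trace: pool -> MLP -> knots -> interpolate
        # -> residual subtraction -> sum
        net = _tiny_net()
        rng = np.random.default_rng(42)
        weights = [rng.uniform(-0.5, 0.5, size=w.shape)
                   for w in net.get_weights()]
        net.set_weights(weights)
        x = np.array([[0.3, -0.2, 0.7, 0.1]])
        outs, _ = net.forward(x, None)

        M = interpolation_matrix(1, 2)  # d=2, H=2 -> single knot
        cur = x.copy()
        total = np.zeros((1, 2))
        for b in range(2):
            W1, b1, W2, b2, Wb, bb, Wf, bf = weights[b * 8:(b + 1) * 8]
            pooled = np.maximum(cur[:, [0, 1]].max(axis=1, keepdims=True),
                                -np.inf)
            pooled = np.stack([cur[:, :2].max(axis=1), cur[:, 2:].max(axis=1)],
                              axis=1)
            h = _relu(_relu(pooled @ W1 + b1) @ W2 + b2)
            backcast = h @ Wb + bb
            knots = h @ Wf + bf
            total = total + knots @ M
            cur = cur - backcast
        np.testing.assert_allclose(outs[0].data, total, atol=1e-12)

    def test_forecast_is_sum_of_block_contributions(self):
        net = _tiny_net()
        x = np.random.default_rng(1).normal(size=(5, 4))
        outs, contribs = net.forward(x, None)
        summed = np.sum([c[0] for c in contribs], axis=0)
        np.testing.assert_allclose(outs[0].data, summed, atol=1e-12)

    def test_doubling_forecast_head_doubles_contribution(self):
        net = _tiny_net()
        x = np.array([[0.5, -0.5, 0.25, 1.0]])
        _, before = net.forward(x, None)
        net.blocks[0].Wfore.data *= 2.0
        net.blocks[0].bfore.data *= 2.0
        _, after = net.forward(x, None)
        np.testing.assert_allclose(after[0][0], 2.0 * before[0][0], atol=1e-12)
        np.testing.assert_allclose(after[1][0], before[1][0], atol=1e-12)

    def test_single_block_no_pool_equals_plain_mlp(self):
        # k=1, d=1, one stack, one block: the model is exactly an MLP
        cfg = NHiTSConfig(lookback=6, horizon=3, n_stacks=1, n_blocks=1,
                          mlp_units=8, pool_kernel_sizes=1,
                          downsample_factors=1, seed=5)
        net = _NHiTSNet(cfg, cov_width=6, out_channels=1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 6))
        z = rng.normal(size=(4, 6))
        outs, _ = net.forward(x, z)
        W1, b1, W2, b2, _, _, Wf, bf = [p.data for p in net.blocks[0].params()]
        inp = np.concatenate([x, z], axis=1)
        mlp = _relu(_relu(inp @ W1 + b1) @ W2 + b2) @ Wf + bf
        np.testing.assert_allclose(outs[0].data, mlp, atol=1e-12)


def _sine_windows(horizon=6, n_days=8, noise=False):
    channels = {"soil_temperature": ChannelSpec(25.0, 2.0, 0.0,
                                                ar1_rho=0.0,
                                                noise_sd=0.1 if noise else 0.0)}
    cfg = SimConfig(n_days=n_days, channels=channels, coupling_beta=0.0,
                    target_channel="soil_temperature",
                    source_channel="soil_temperature", seed=3)
    s = generate(cfg)
    scaled, _ = fit_apply_minmax(s, len(s))
    return windows_to_arrays(make_windows(scaled, "soil_temperature", [],
                                          12, horizon))


class TestTraining:
    def test_constant_target_converges_fast(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(512, 8))
        y = np.full((512, 2), 0.5)
        m = NHiTSRegressor(lookback=8, n_stacks=1, mlp_units=16,
                           pool_kernel_sizes=2, downsample_factors=1,
                           learning_rate=0.01, max_epochs=30, patience=30,
                           random_state=0)
        m.fit(X, y)
        assert m.history_.train_loss[-1] < 0.02

    def test_same_seed_identical_history(self):
        X, y = _sine_windows(horizon=3, n_days=4)
        kw = dict(lookback=12, mlp_units=16, max_epochs=5, random_state=7)
        a = NHiTSRegressor(**kw).fit(X, y)
        b = NHiTSRegressor(**kw).fit(X, y)
        assert a.history_.train_loss == b.history_.train_loss
        assert a.history_.val_loss == b.history_.val_loss

    def test_flat_validation_stops_at_patience_exhaustion(self):
        X, y = _sine_windows(horizon=3, n_days=4)
        # zero learning rate -> validation loss can never improve
        m = NHiTSRegressor(lookback=12, mlp_units=8, learning_rate=0.0,
                           max_epochs=100, patience=5, random_state=0)
        m.fit(X, y)
        assert m.history_.n_epochs == 6  # epoch 0 sets the best, then 5 flat

    def test_noiseless_sinusoid_learned_accurately(self):
        X, y = _sine_windows(horizon=6, n_days=8)
        m = NHiTSRegressor(lookback=12, mlp_units=64, batch_size=128,
                           max_epochs=150, patience=25, random_state=0)
        m.fit(X, y)
        mae = np.mean(np.abs(m.predict(X) - y))
        assert mae < 0.05  # scaled units

    def test_empty_data_rejected(self):
        m = NHiTSRegressor(lookback=4)
        with pytest.raises(ValueError):
            m.fit(np.empty((0, 4)), np.empty((0, 2)))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _sine_windows(horizon=3, n_days=4)
        m = NHiTSRegressor(lookback=12, mlp_units=16, max_epochs=3,
                           random_state=1)
        m.fit(X, y)
        m.save(str(tmp_path / "ckpt"))
        back, scaling = load_forecaster(str(tmp_path / "ckpt"))
        assert scaling is None
        np.testing.assert_allclose(back.predict(X[:5]), m.predict(X[:5]),
                                   atol=1e-12)
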
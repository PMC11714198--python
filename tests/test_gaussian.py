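import numpy as np
import pytest
from scipy.stats import norm

from soilcast import (GaussianForecast, IntervalForecast, gaussian_heads,
                      gaussian_nll, mc_intervals, pinball_loss,
                      interval_from_errors, NHiTSGaussianForecaster,
                      NHiTSQuantileForecaster, ResidualIntervalForecaster,
                      NHiTSRegressor)
from soilcast.gaussian import SIGMA_FLOOR


class TestGaussianHeads:
    def test_softplus_at_zero(self):
        fc = gaussian_heads(np.zeros(3), np.zeros((3, 2)), 0.0,
                            np.zeros((3, 2)), 0.0)
        np.testing.assert_allclose(fc.sigma, np.log(2.0) + SIGMA_FLOOR)

    def test_sigma_floored_never_zero(self):
        fc = gaussian_heads(np.ones(2), np.zeros((2, 1)), 0.0,
                            np.zeros((2, 1)), -1e4)
        assert np.all(fc.sigma >= SIGMA_FLOOR) and np.all(fc.sigma > 0)

    def test_mu_is_affine(self):
        rng = np.random.default_rng(0)
        ht = rng.normal(size=4)
        w, b = rng.normal(size=(4, 3)), rng.normal(size=3)
        a = gaussian_heads(ht, w, b, w, 0.0)
        d = gaussian_heads(2 * ht, w, b, w, 0.0)
        np.testing.assert_allclose(d.mu - a.mu, ht @ w, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            gaussian_heads(np.array([np.nan]), np.ones((1, 1)), 0.0,
                           np.ones((1, 1)), 0.0)


class TestGaussianNLL:
    def test_closed_form_at_mean(self):
        fc = GaussianForecast(mu=np.zeros(5), sigma=np.ones(5))
        assert gaussian_nll(np.zeros(5), fc) == pytest.approx(
            0.5 * np.log(2 * np.pi))

    def test_minimized_at_mu_equals_target(self):
        c = np.array([1.3])
        base = gaussian_nll(c, GaussianForecast(c.copy(), np.ones(1)))
        for shift in (-0.5, 0.2, 1.0):
            assert gaussian_nll(c, GaussianForecast(c + shift,
                                                    np.ones(1))) > base

    def test_matches_density_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            c = rng.normal(size=4)
            mu = rng.normal(size=4)
            sigma = rng.uniform(0.1, 3.0, size=4)
            got = gaussian_nll(c, GaussianForecast(mu, sigma))
            want = -norm.logpdf(c, loc=mu, scale=sigma).mean()
            assert abs(got - want) < 1e-10

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_nll([0.0], GaussianForecast(np.zeros(1), np.zeros(1)))


class TestMCIntervals:
    def test_degenerate_sigma_collapses(self):
        fc = GaussianForecast(mu=np.array([2.0, 3.0]), sigma=np.zeros(2))
        iv = mc_intervals(fc, n_samples=100, seed=0)
        np.testing.assert_array_equal(iv.lower, fc.mu)
        np.testing.assert_array_equal(iv.median, fc.mu)
        np.testing.assert_array_equal(iv.upper, fc.mu)

    def test_bounds_match_gaussian_quantiles(self):
        mu, sigma = 1.0, 0.7
        fc = GaussianForecast(mu=np.full(3, mu), sigma=np.full(3, sigma))
        iv = mc_intervals(fc, n_samples=10_000, level=0.90, seed=1)
        z = norm.ppf(0.95)
        assert np.all(np.abs(iv.lower - (mu - z * sigma)) < 0.05 * sigma)
        assert np.all(np.abs(iv.upper - (mu + z * sigma)) < 0.05 * sigma)
        assert np.all(np.abs(iv.median - mu) < 0.05 * sigma)

    def test_seeded_reproducibility(self):
        fc = GaussianForecast(mu=np.zeros(2), sigma=np.ones(2))
        a = mc_intervals(fc, n_samples=50, seed=9)
        b = mc_intervals(fc, n_samples=50, seed=9)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_width_scales_with_sigma(self):
        fc1 = GaussianForecast(mu=np.zeros(1), sigma=np.ones(1))
        fc3 = GaussianForecast(mu=np.zeros(1), sigma=np.full(1, 3.0))
        w1 = mc_intervals(fc1, n_samples=20_000, seed=2)
        w3 = mc_intervals(fc3, n_samples=20_000, seed=2)
        ratio = (w3.upper - w3.lower) / (w1.upper - w1.lower)
        assert abs(ratio[0] - 3.0) < 0.2

    def test_invalid_args_rejected(self):
        fc = GaussianForecast(np.zeros(1), np.ones(1))
        with pytest.raises(ValueError):
            mc_intervals(fc, n_samples=1)
        with pytest.raises(ValueError):
            mc_intervals(fc, level=1.0)


class TestPinballLoss:
    def test_zero_at_perfect_prediction(self):
        assert pinball_loss([1.0, 2.0], [1.0, 2.0], 0.5) == 0.0

    def test_median_case_is_half_abs_error(self):
        c, p = np.array([3.0, 0.0]), np.array([1.0, 1.0])
        assert pinball_loss(c, p, 0.5) == pytest.approx(
            0.5 * np.mean(np.abs(c - p)))

    def test_asymmetry_ratio(self):
        q = 0.9
        under = pinball_loss([1.0], [0.0], q)   # prediction below target
        over = pinball_loss([0.0], [1.0], q)    # prediction above target
        assert under / over == pytest.approx(q / (1 - q))


class TestIntervalOrdering:
    def test_violating_bounds_rejected(self):
        with pytest.raises(ValueError):
            IntervalForecast(lower=[1.0], median=[0.0], upper=[2.0])


class TestResidualConstructors:
    def test_zero_residuals_degenerate(self):
        pred = np.zeros((20, 2))
        ctor, offsets = interval_from_errors(pred, pred, method="error_fit")
        np.testing.assert_allclose(offsets, 0.0, atol=1e-12)
        iv = ctor(np.ones((3, 2)))
        np.testing.assert_allclose(iv.lower, iv.upper)

    @pytest.mark.parametrize("method", ["error_fit", "bootstrap"])
    def test_symmetric_residuals_give_symmetric_interval(self, method):
        rng = np.random.default_rng(4)
        resid = rng.normal(size=500)
        resid = np.concatenate([resid, -resid])[:, None]  # exactly symmetric
        pred = np.zeros((1000, 1))
        ctor, offsets = interval_from_errors(pred, resid, method=method, seed=0)
        assert abs(offsets[0, 0] + offsets[0, 2]) < 0.1
        assert abs(offsets[0, 1]) < 0.05

    @pytest.mark.parametrize("method", ["error_fit", "bootstrap"])
    def test_coverage_on_well_specified_residuals(self, method):
        # validation and test residuals drawn from the same Gaussian:
        # empirical coverage must sit near the nominal level
        rng = np.random.default_rng(5)
        val_resid = rng.normal(0, 0.5, size=(800, 1))
        ctor, _ = interval_from_errors(np.zeros((800, 1)), val_resid,
                                       method=method, level=0.90, seed=1)
        test_obs = rng.normal(0, 0.5, size=(2000, 1))
        iv = ctor(np.zeros((2000, 1)))
        picp = np.mean((test_obs >= iv.lower) & (test_obs <= iv.upper))
        assert 0.83 <= picp <= 0.97

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError, match="10"):
            interval_from_errors(np.zeros((5, 1)), np.ones((5, 1)))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            interval_from_errors(np.zeros((20, 1)), np.ones((20, 1)),
                                 method="magic")


def _ar1_windows(horizon, seed=0, n=600):
    rng = np.random.default_rng(seed)
    e = np.zeros(n)
    for t in range(1, n):
        e[t] = 0.8 * e[t - 1] + rng.normal(0, 0.1)
    y = 0.5 + e
    T0 = 8
    X = np.stack([y[i:i + T0] for i in range(n - T0 - horizon + 1)])
    Y = np.stack([y[i + T0:i + T0 + horizon]
                  for i in range(n - T0 - horizon + 1)])
    return X, Y


class TestGaussianForecaster:
    def test_sigma_positive_and_interval_ordered(self):
        X, y = _ar1_windows(3)
        m = NHiTSGaussianForecaster(lookback=8, mlp_units=16, batch_size=64,
                                    max_epochs=10, random_state=0)
        m.fit(X, y)
        dist = m.predict_dist(X[:20])
        assert np.all(dist.sigma > 0)
        iv = m.predict_interval(X[:20])
        assert np.all(iv.lower <= iv.median + 1e-12)
        assert np.all(iv.median <= iv.upper + 1e-12)

    def test_sigma_shrinks_on_noiseless_data(self):
        t = np.arange(500)
        y = 0.5 + 0.4 * np.sin(2 * np.pi * t / 72)
        T0, H = 8, 2
        X = np.stack([y[i:i + T0] for i in range(400)])
        Y = np.stack([y[i + T0:i + T0 + H] for i in range(400)])
        short = NHiTSGaussianForecaster(lookback=8, mlp_units=32,
                                        batch_size=64, max_epochs=2,
                                        patience=100, random_state=0)
        long = NHiTSGaussianForecaster(lookback=8, mlp_units=32,
                                       batch_size=64, max_epochs=120,
                                       patience=100, random_state=0)
        short.fit(X, Y)
        long.fit(X, Y)
        assert (np.median(long.predict_dist(X).sigma)
                < 0.25 * np.median(short.predict_dist(X).sigma))

    def test_deterministic_history(self):
        X, y = _ar1_windows(2)
        kw = dict(lookback=8, mlp_units=16, max_epochs=4, random_state=3)
        a = NHiTSGaussianForecaster(**kw).fit(X, y)
        b = NHiTSGaussianForecaster(**kw).fit(X, y)
        assert a.history_.val_loss == b.history_.val_loss

    def test_point_forecast_is_interval_median(self):
        X, y = _ar1_windows(2)
        m = NHiTSGaussianForecaster(lookback=8, mlp_units=16, max_epochs=3,
                                    random_state=0)
        m.fit(X, y)
        np.testing.assert_array_equal(m.predict(X[:4]),
                                      m.predict_interval(X[:4]).median)


class TestQuantileForecaster:
    def test_interval_ordered_and_quantiles_set(self):
        X, y = _ar1_windows(2)
        m = NHiTSQuantileForecaster(lookback=8, mlp_units=16, max_epochs=8,
                                    level=0.90, random_state=0)
        assert m.quantiles == pytest.approx((0.05, 0.5, 0.95))
        m.fit(X, y)
        iv = m.predict_interval(X[:10])
        assert np.all(iv.lower <= iv.median) and np.all(iv.median <= iv.upper)


class TestResidualForecaster:
    def test_fit_predict_interval(self):
        X, y = _ar1_windows(2)
        base = NHiTSRegressor(lookback=8, mlp_units=16, max_epochs=8,
                              random_state=0)
        m = ResidualIntervalForecaster(base_estimator=base, method="bootstrap",
                                       level=0.9, random_state=0)
        m.fit(X, y)
        iv = m.predict_interval(X[:12])
        assert iv.lower.shape == (12, 2)
        assert np.all(iv.lower <= iv.upper)
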
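"""GP imputation against closed-form posteriors and coverage checks."""

import numpy as np
import pytest

from microdyn import ImputationError, TimeSeries, gp_fit, gp_predict, impute
from microdyn.imputation import gp_posterior_variance


def gp_posterior_oracle(t_train, y_train, t_query, ls, sig2, noise2):
    """Closed-form zero-mean GP posterior with an RBF kernel."""
    def k(a, b):
        return sig2 * np.exp(-0.5 * (a[:, None] - b[None, :]) ** 2 / ls**2)

    K = k(t_train, t_train) + noise2 * np.eye(len(t_train))
    Ks = k(t_query, t_train)
    Kinv = np.linalg.inv(K)
    mean = Ks @ Kinv @ y_train
    var = sig2 + noise2 - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, var


@pytest.fixture()
def sine_series():
    t = np.linspace(0, 10, 40)
    return TimeSeries(times=t, values=np.sin(t)[:, None], names=["sp"])


class TestGpFit:
    def test_constant_series_predicts_constant(self):
        t = np.linspace(0, 5, 12)
        ts = TimeSeries(times=t, values=np.full((12, 1), 3.7))
        fit = gp_fit(ts, seed=0)
        mean, _, _ = gp_predict(fit, np.linspace(0, 5, 30))
        assert np.allclose(mean, 3.7, atol=1e-6)

    def test_noiseless_sine_interpolated_below_1e3(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        mean, _, _ = gp_predict(fit, sine_series.times)
        assert np.abs(mean[:, 0] - sine_series.values[:, 0]).max() < 1e-3

    def test_optimizer_improves_log_marginal_likelihood(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        h = fit.hyperparameters["sp"]
        assert (
            h["log_marginal_likelihood"]
            >= h["initial_log_marginal_likelihood"] - 1e-9
        )

    def test_single_observation_rejected_with_name(self):
        vals = np.array([[1.0, 1.0], [np.nan, 2.0], [np.nan, 3.0]])
        ts = TimeSeries(times=[0, 1, 2], values=vals, names=["lonely", "ok"])
        with pytest.raises(ImputationError, match="lonely"):
            gp_fit(ts, seed=0)

    def test_matches_closed_form_posterior_oracle(self):
        # fixed hyperparameters: compare sklearn's machinery to the textbook
        # formulas through our prediction path
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import (
            RBF,
            ConstantKernel,
            WhiteKernel,
        )
        from microdyn.imputation import GPFit

        rng = np.random.default_rng(3)
        t_train = np.sort(rng.uniform(0, 10, 9))
        y_train = np.sin(t_train) + 0.1 * rng.normal(size=9)
        ls, sig2, noise2 = 1.3, 0.8, 0.01
        kernel = ConstantKernel(sig2, "fixed") * RBF(ls, "fixed") + WhiteKernel(
            noise2, "fixed"
        )
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                      optimizer=None)
        gp.fit(t_train.reshape(-1, 1), y_train)
        fit = GPFit(kernel="rbf", names=["v"], models={"v": gp},
                    train_times={"v": t_train}, train_values={"v": y_train})
        t_query = np.linspace(-1, 11, 25)
        mean, lo, hi = gp_predict(fit, t_query, level=0.95)
        m_or, v_or = gp_posterior_oracle(t_train, y_train, t_query, ls, sig2,
                                         noise2)
        assert np.abs(mean[:, 0] - m_or).max() < 1e-8
        band_or = 1.959963984540054 * np.sqrt(v_or)
        assert np.abs((hi - lo)[:, 0] / 2 - band_or).max() < 1e-6

    def test_one_training_point_closed_form(self):
        # single observation (t0, y0), RBF: mean(t) = k(t,t0)/(sig2+noise2)*y0
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import (
            RBF,
            ConstantKernel,
            WhiteKernel,
        )

        ls, sig2, noise2, y0 = 2.0, 1.5, 0.1, 2.5
        kernel = ConstantKernel(sig2, "fixed") * RBF(ls, "fixed") + WhiteKernel(
            noise2, "fixed"
        )
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None)
        gp.fit([[0.0]], [y0])
        t = np.array([1.7])
        mu, sd = gp.predict(t.reshape(-1, 1), return_std=True)
        kts = sig2 * np.exp(-0.5 * t**2 / ls**2)
        # sklearn adds 1e-10 jitter to the kernel diagonal
        assert mu[0] == pytest.approx(kts[0] * y0 / (sig2 + noise2), abs=1e-8)
        var_expected = sig2 + noise2 - kts[0] ** 2 / (sig2 + noise2)
        assert sd[0] ** 2 == pytest.approx(var_expected, abs=1e-8)


class TestGpPredict:
    def test_interpolation_at_training_points_with_tiny_noise(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        mean, lo, hi = gp_predict(fit, sine_series.times, level=0.95)
        # noiseless data: fitted noise floor is tiny, band collapses
        assert np.abs(mean[:, 0] - sine_series.values[:, 0]).max() < 1e-3
        assert (hi - lo).max() < 0.05

    def test_reversion_to_prior_far_from_data(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        far = np.array([1e4])
        mean, _, _ = gp_predict(fit, far)
        assert mean[0, 0] == pytest.approx(fit.prior_mean("sp"), abs=1e-6)
        var = gp_posterior_variance(fit, far)[0, 0]
        assert var == pytest.approx(fit.prior_variance("sp"), rel=1e-6)

    def test_posterior_variance_never_exceeds_prior(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        q = np.linspace(-20, 30, 200)
        var = gp_posterior_variance(fit, q)[:, 0]
        assert (var <= fit.prior_variance("sp") * (1 + 1e-9)).all()

    def test_band_nesting_across_levels(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        q = np.linspace(0, 10, 50)
        _, lo95, hi95 = gp_predict(fit, q, level=0.95)
        _, lo50, hi50 = gp_predict(fit, q, level=0.5)
        assert (lo95 <= lo50).all() and (hi50 <= hi95).all()

    def test_empty_query_rejected(self, sine_series):
        fit = gp_fit(sine_series, seed=0)
        with pytest.raises(ValueError):
            gp_predict(fit, [])

    def test_band_coverage_on_synthetic_gp_draws(self):
        """95% bands cover held-out points from a known GP at 0.88-0.99."""
        rng = np.random.default_rng(17)
        ls, sig2, noise2 = 1.5, 1.0, 0.05
        n_rep, n_train, n_test = 10, 30, 20
        hits, total = 0, 0
        for _ in range(n_rep):
            t = np.sort(rng.uniform(0, 12, n_train + n_test))
            K = sig2 * np.exp(-0.5 * (t[:, None] - t[None, :]) ** 2 / ls**2)
            f = rng.multivariate_normal(np.zeros(t.size),
                                        K + 1e-10 * np.eye(t.size))
            y = f + np.sqrt(noise2) * rng.normal(size=t.size)
            test_ix = rng.choice(t.size, n_test, replace=False)
            train_m = np.ones(t.size, bool)
            train_m[test_ix] = False
            ts = TimeSeries(times=t[train_m], values=y[train_m, None])
            fit = gp_fit(ts, seed=1)
            _, lo, hi = gp_predict(fit, t[~train_m], level=0.95)
            hits += int(((y[~train_m] >= lo[:, 0]) & (y[~train_m] <= hi[:, 0])).sum())
            total += n_test
        rate = hits / total
        assert 0.88 <= rate <= 0.99


class TestImpute:
    def test_no_missing_is_identity(self, sine_series):
        out = impute(sine_series, seed=0)
        assert np.array_equal(out.values, sine_series.values)

    def test_linear_trend_gap_filled_within_5_percent(self):
        t = np.linspace(0, 10, 25)
        y = 2.0 * t + 1.0
        vals = y[:, None].copy()
        vals[12, 0] = np.nan
        ts = TimeSeries(times=t, values=vals)
        out = impute(ts, seed=0)
        true = 2.0 * t[12] + 1.0
        assert abs(out.values[12, 0] - true) / true < 0.05

    def test_completeness_and_observed_bit_identity(self, rng):
        t = np.arange(30.0)
        vals = np.column_stack([np.sin(t / 3), np.cos(t / 4)])
        vals += 0.05 * rng.normal(size=vals.shape)
        holes = rng.random(vals.shape) < 0.15
        vals_missing = vals.copy()
        vals_missing[holes] = np.nan
        ts = TimeSeries(times=t, values=vals_missing)
        out = impute(ts, seed=2)
        assert out.mask.all()
        # observed entries untouched, bit for bit
        assert np.array_equal(out.values[~holes], vals[~holes])
        assert "imputed" in out.meta
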
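"""Isotope incorporation model, turnover fitting, and derived quantities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from compgrowth.simulate import simulate_isotope_observations
from compgrowth.turnover import (
    FitError,
    IsotopeSeries,
    NitrogenTurnoverModel,
    bootstrap_fit,
    contribution_split,
    decompose_series,
    fit_metabolic_turnover,
    growth_rate_k,
    half_time,
    predict_d15n,
    replicate_fits,
)
from conftest import C0, CN, FIT_DAYS, make_series

rates = st.floats(0.001, 0.2, allow_nan=False)


def grid_search_m(series, k, window=(7, 35), step=1e-5, m_max=0.2):
    """Brute-force oracle: 1-D scan of the sum of squares over m."""
    mask = (series.t >= window[0]) & (series.t <= window[1])
    t, y = series.t[mask], series.d15n[mask]
    grid = np.arange(0.0, m_max + step, step)
    pred = series.cn + (series.c0 - series.cn) * np.exp(
        -np.outer(grid, t) - k * t
    )
    sse = ((pred - y) ** 2).sum(axis=1)
    return grid[int(np.argmin(sse))]


class TestModelFunctions:
    def test_t_zero_gives_baseline(self):
        assert predict_d15n(8.53, 14.31, 0.05, 0.02, 0.0) == 8.53

    def test_zero_rates_stay_at_baseline(self):
        t = np.array([0.0, 5.0, 50.0])
        assert np.allclose(predict_d15n(8.53, 14.31, 0.0, 0.0, t), 8.53)

    def test_mid_trial_value(self):
        # 14.31 - 5.78 e^(-0.084 * 14)
        assert predict_d15n(8.53, 14.31, 0.051, 0.033, 14) == pytest.approx(
            12.53, abs=0.005
        )

    @pytest.mark.parametrize(
        "w0,w1,days,expected",
        [(0.5, 0.5 * np.e, 1, 1.0), (0.81, 3.38, 28, 0.0510), (0.44, 3.38, 35, 0.0583)],
    )
    def test_growth_rate_values(self, w0, w1, days, expected):
        assert growth_rate_k(w0, w1, days) == pytest.approx(expected, abs=1e-4)

    def test_growth_rate_rejects_bad_inputs(self):
        for args in [(0, 1, 1), (1, -1, 1), (1, 2, 0)]:
            with pytest.raises(ValueError):
                growth_rate_k(*args)

    @pytest.mark.parametrize(
        "k,m,expected",
        [(0.051, 0.033, 8.25), (0.061, 0.008, 10.05), (np.log(2), 0.0, 1.0)],
    )
    def test_half_time_values(self, k, m, expected):
        assert half_time(k, m) == pytest.approx(expected, abs=0.005)

    def test_half_time_rejects_zero_rates(self):
        with pytest.raises(ValueError):
            half_time(0.0, 0.0)

    @given(k=rates, m=rates, dk=st.floats(1e-4, 0.05))
    def test_half_time_strictly_decreasing_in_each_rate(self, k, m, dk):
        assert half_time(k + dk, m) < half_time(k, m)
        assert half_time(k, m + dk) < half_time(k, m)

    @pytest.mark.parametrize(
        "k,m,expected",
        [(0.061, 0.008, (88.4, 11.6)), (0.051, 0.033, (60.7, 39.3)), (0.02, 0.02, (50, 50))],
    )
    def test_contribution_values(self, k, m, expected):
        got = contribution_split(k, m)
        assert got[0] == pytest.approx(expected[0], abs=0.05)
        assert got[1] == pytest.approx(expected[1], abs=0.05)

    @given(k=rates, m=st.floats(0.0, 0.2))
    def test_contributions_normalised(self, k, m):
        gk, gm = contribution_split(k, m)
        assert gk + gm == pytest.approx(100.0, abs=1e-9)
        assert 0.0 <= gk <= 100.0 and 0.0 <= gm <= 100.0


class TestFit:
    def test_zero_noise_closure(self):
        series = make_series("x", 0.057, 0.018, noise_sd=0.0)
        fit = fit_metabolic_turnover(series, k=0.057)
        assert abs(fit.m_hat - 0.018) <= 1e-6
        assert fit.t50 == pytest.approx(half_time(0.057, fit.m_hat), abs=1e-12)

    def test_matches_grid_search_oracle(self, fixture_series):
        for k, series in fixture_series:
            fit = fit_metabolic_turnover(series, k)
            oracle = grid_search_m(series, k)
            assert abs(fit.m_hat - oracle) <= 2e-5

    def test_boundary_estimate_flagged_not_negative(self):
        # generating m = 0: the bounded fit must sit at zero with a flag
        series = make_series("x", 0.06, 0.0, noise_sd=0.0)
        fit = fit_metabolic_turnover(series, k=0.06)
        assert fit.m_hat == 0.0
        assert fit.at_boundary
        assert fit.converged

    def test_requires_three_distinct_timepoints(self):
        series = IsotopeSeries("x", [7, 7, 9, 9], [10, 10.1, 11, 11.2], C0, CN)
        with pytest.raises(FitError, match="distinct time points"):
            fit_metabolic_turnover(series, k=0.05)

    def test_window_restricts_observations(self):
        series = make_series("x", 0.051, 0.033, noise_sd=0.0, days=(0, 3, 6, *FIT_DAYS))
        fit = fit_metabolic_turnover(series, k=0.051, window=(7, 35))
        assert fit.n_obs == 3 * len(FIT_DAYS)
        assert fit.fit_window == (7.0, 35.0)

    def test_cn_coestimation_recovers_asymptote(self):
        series = make_series("x", 0.051, 0.033, noise_sd=0.0)
        series.cn = None
        fit = fit_metabolic_turnover(series, k=0.051)
        assert fit.cn_estimated
        assert fit.cn_used == pytest.approx(14.31, abs=1e-4)
        assert fit.m_hat == pytest.approx(0.033, abs=1e-4)

    def test_standard_error_positive_on_noisy_series(self):
        fit = fit_metabolic_turnover(make_series("x", 0.051, 0.033, seed=3), k=0.051)
        assert 0 < fit.m_se < 0.05

    def test_replicate_fits_one_per_replicate(self):
        series = make_series("x", 0.051, 0.033, seed=5)
        fits = replicate_fits(series, k=0.051)
        assert len(fits) == 3
        pooled = fit_metabolic_turnover(series, k=0.051)
        assert np.mean([f.m_hat for f in fits]) == pytest.approx(pooled.m_hat, abs=0.01)


class TestEstimatorAPI:
    def test_sklearn_contract(self):
        est = NitrogenTurnoverModel(k=0.051)
        params = est.get_params()
        assert params["k"] == 0.051 and params["cn"] == 14.31
        cloned = clone(est).set_params(m_max=0.3)
        assert cloned.get_params()["m_max"] == 0.3

    def test_predict_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            NitrogenTurnoverModel(k=0.051).predict([7, 14])

    def test_fit_predict_roundtrip(self):
        series = make_series("x", 0.051, 0.033, noise_sd=0.0)
        est = NitrogenTurnoverModel(k=0.051).fit(series.t, series.d15n)
        assert np.allclose(est.predict(series.t[series.t >= 7]),
                           series.d15n[series.t >= 7], atol=1e-6)
        assert est.score(series.t[series.t >= 7], series.d15n[series.t >= 7]) > 0.999

    def test_column_vector_input(self):
        series = make_series("x", 0.051, 0.033, seed=1)
        est = NitrogenTurnoverModel(k=0.051).fit(series.t.reshape(-1, 1), series.d15n)
        assert est.m_ > 0


class TestBootstrap:
    def test_zero_noise_gives_zero_spread(self):
        series = make_series("x", 0.051, 0.033, noise_sd=0.0)
        boot = bootstrap_fit(series, 0.051, n_boot=100, seed=0)
        assert boot.m_se == pytest.approx(0.0, abs=1e-9)

    def test_spread_grows_with_noise(self):
        lo = bootstrap_fit(make_series("x", 0.051, 0.033, 0.1, seed=2), 0.051,
                           n_boot=150, seed=1)
        hi = bootstrap_fit(make_series("x", 0.051, 0.033, 0.4, seed=2), 0.051,
                           n_boot=150, seed=1)
        assert hi.m_se > lo.m_se

    def test_deterministic_under_seed(self):
        series = make_series("x", 0.051, 0.033, seed=4)
        a = bootstrap_fit(series, 0.051, n_boot=100, seed=7)
        b = bootstrap_fit(series, 0.051, n_boot=100, seed=7)
        assert np.array_equal(a.m_samples, b.m_samples)

    def test_rejects_small_n_boot(self):
        with pytest.raises(ValueError):
            bootstrap_fit(make_series("x", 0.051, 0.033), 0.051, n_boot=50)


class TestDecomposition:
    def test_zero_m_collapses_columns(self):
        series = make_series("x", 0.06, 0.0, noise_sd=0.0)
        fit = fit_metabolic_turnover(series, k=0.06)
        dec = decompose_series(fit, series)
        assert np.allclose(dec["predicted_k_plus_m"], dec["predicted_k_only"])

    def test_day_zero_columns_equal_baseline(self):
        series = make_series("x", 0.051, 0.033, noise_sd=0.0, days=(0, *FIT_DAYS))
        fit = fit_metabolic_turnover(series, k=0.051)
        dec = decompose_series(fit, series)
        at0 = dec[dec["day"] == 0]
        assert np.allclose(at0[["observed", "predicted_k_plus_m", "predicted_k_only"]], C0)

    def test_growth_only_curve_lags_full_model(self):
        series = make_series("x", 0.051, 0.033, noise_sd=0.0)
        fit = fit_metabolic_turnover(series, k=0.051)
        dec = decompose_series(fit, series)
        pos = dec[dec["day"] > 0]
        assert (pos["predicted_k_only"] < pos["predicted_k_plus_m"]).all()
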
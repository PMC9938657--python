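"""Generator behaviour: closed-form trajectories, noise models, determinism."""

import numpy as np
import pandas as pd
import pytest

from compgrowth.config import SimConfig, TreatmentConfig
from compgrowth.diversity import shannon_index
from compgrowth.simulate import (
    simulate_cohort,
    simulate_feed_intake,
    simulate_isotope_observations,
    simulate_isotope_series,
    simulate_otu_table,
    simulate_weights,
)


def day_stepping_weight(w0, cfg, t):
    """Brute-force oracle: multiply daily growth factors in small steps."""
    dt = 1e-3
    w = w0
    for i in range(int(t / dt)):
        day = i * dt
        if cfg.restriction_days == 0:
            k = cfg.base_k
        elif day < cfg.restriction_days:
            k = cfg.restricted_k
        elif day < cfg.recovery_end_day:
            k = cfg.compensatory_k
        else:
            k = cfg.base_k
        w *= np.exp(k * dt)
    return w


class TestWeights:
    def test_control_closed_form(self, control, noiseless_sim):
        w = simulate_weights(control, noiseless_sim, days=[0, 35])
        final = w.loc[w["day"] == 35, "weight_g"].unique()
        expected = 0.44 * np.exp(0.0583 * 35)
        assert np.allclose(final, expected)
        assert expected == pytest.approx(3.38, abs=0.01)
        # independent oracle: day-stepping multiplication
        assert day_stepping_weight(0.44, control, 35) == pytest.approx(expected, rel=1e-4)

    def test_no_restriction_degenerates_to_control(self, control, noiseless_sim):
        degenerate = TreatmentConfig(
            name="R0", restriction_days=0, restricted_k=0.02, compensatory_k=0.07
        )
        days = [0, 3, 6, 9, 14, 21, 28, 35]
        w_ctrl = simulate_weights(control, noiseless_sim, days=days)
        w_r0 = simulate_weights(degenerate, noiseless_sim, days=days)
        assert np.allclose(w_ctrl["weight_g"], w_r0["weight_g"])

    def test_restricted_below_control_then_converges(self, control, t6, noiseless_sim):
        days = [0, 7, 35]
        ctrl = simulate_weights(control, noiseless_sim, days=days)
        rest = simulate_weights(t6, noiseless_sim, days=days)
        w = lambda df, d: df.loc[df["day"] == d, "weight_g"].iloc[0]
        assert w(rest, 7) < w(ctrl, 7)
        # phase-schedule oracle for both treatments at day 7
        assert w(rest, 7) == pytest.approx(0.44 * np.exp(0.020 * 6 + 0.0666 * 1))
        assert w(ctrl, 7) == pytest.approx(0.44 * np.exp(0.0583 * 7))
        # full catch-up by day 35: within 5% of control
        assert w(rest, 35) == pytest.approx(w(ctrl, 35), rel=0.05)

    def test_monotone_increasing_without_noise(self, t6, noiseless_sim):
        days = np.arange(0, 36)
        w = simulate_weights(t6, noiseless_sim, days=days)
        traj = w[(w["tank"] == "T6-1") & (w["individual"] == 1)].sort_values("day")
        assert np.all(np.diff(traj["weight_g"]) > 0)

    def test_rejects_nonpositive_initial_weight(self, control):
        with pytest.raises(ValueError):
            SimConfig(initial_weight_mean=0.0)

    def test_deterministic_under_seed(self, control):
        sim = SimConfig(seed=5)
        a = simulate_weights(control, sim)
        b = simulate_weights(control, sim)
        pd.testing.assert_frame_equal(a, b)


class TestIsotopes:
    def test_day_zero_is_baseline(self, control, noiseless_sim):
        s = simulate_isotope_series(control, noiseless_sim)
        assert np.allclose(s.d15n[s.t == 0], noiseless_sim.d15n_baseline)

    def test_direct_model_value(self):
        # k + m = 0.084 at t = 35: 14.31 + (8.53 - 14.31) e^(-2.94)
        t, y = simulate_isotope_observations(
            8.53, 14.31, 0.051, 0.033, [35], n_reps=1, noise_sd=0.0
        )
        assert y[0] == pytest.approx(14.31 - 5.78 * np.exp(-2.94), abs=1e-9)
        assert y[0] == pytest.approx(14.00, abs=0.005)

    def test_noise_sd_calibration(self):
        t, y = simulate_isotope_observations(
            8.53, 14.31, 0.051, 0.033, [14], n_reps=1000, noise_sd=0.2, rng=42
        )
        assert 0.18 <= np.std(y, ddof=1) <= 0.22

    def test_bounded_and_monotone_without_noise(self, t6, noiseless_sim):
        s = simulate_isotope_series(t6, noiseless_sim)
        days = np.unique(s.t)
        means = np.array([s.d15n[s.t == d].mean() for d in days])
        inner = means[days > 0]
        assert np.all(inner > noiseless_sim.d15n_baseline)
        assert np.all(inner < noiseless_sim.d15n_asymptote)
        assert np.all(np.diff(means) > 0)

    def test_rejects_negative_noise_sd(self):
        with pytest.raises(ValueError):
            simulate_isotope_observations(8.53, 14.31, 0.05, 0.02, [7], noise_sd=-0.1)

    def test_enrichment_offset_applies_during_restriction(self, noiseless_sim):
        cfg = TreatmentConfig(
            name="T6e", restriction_days=6, restricted_k=0.02, compensatory_k=0.07,
            d15n_enrichment_offset=0.5,
        )
        base = TreatmentConfig(
            name="T6", restriction_days=6, restricted_k=0.02, compensatory_k=0.07
        )
        s_off = simulate_isotope_series(cfg, noiseless_sim)
        s_base = simulate_isotope_series(base, noiseless_sim)
        in_restriction = s_off.t < 6
        assert np.allclose(s_off.d15n[in_restriction] - s_base.d15n[in_restriction], 0.5)
        assert np.allclose(s_off.d15n[~in_restriction], s_base.d15n[~in_restriction])


class TestFeed:
    def test_restriction_day_fraction(self, t6):
        # baseline 0.11 cut by 70% -> 0.033 of biomass
        assert t6.ration_fraction(0) == pytest.approx(0.11 * 0.3)

    def test_control_constant_fraction(self, control, noiseless_sim):
        feed = simulate_feed_intake(control, noiseless_sim)
        biomass0 = noiseless_sim.shrimp_per_tank * noiseless_sim.initial_weight_mean
        tank = feed[feed["tank"] == "Control-1"].sort_values("day")
        expected = 0.11 * biomass0 * np.exp(0.0583 * tank["day"].to_numpy())
        assert np.allclose(tank["feed_g"], expected)

    def test_restricted_total_below_control(self, control, t6, noiseless_sim):
        total = lambda cfg: (
            simulate_feed_intake(cfg, noiseless_sim).groupby("tank")["feed_g"].sum().iloc[0]
        )
        assert total(t6) < total(control)


class TestOtuTables:
    def test_single_otu_profile_has_zero_shannon(self):
        table = simulate_otu_table(
            4, taxa_profile=np.array([1.0, 0.0, 0.0]), depth=500, seed=0
        )
        for s in table.samples:
            assert shannon_index(table.counts[s].to_numpy()) == 0.0

    def test_uniform_profile_approaches_max_entropy(self):
        table = simulate_otu_table(
            3,
            taxa_profile=np.full(10, 0.1),
            depth=200_000,
            seed=1,
            concentration=1e6,  # tiny overdispersion
        )
        for s in table.samples:
            assert shannon_index(table.counts[s].to_numpy()) == pytest.approx(
                np.log(10), abs=0.01
            )

    def test_column_sums_equal_depth(self):
        table = simulate_otu_table(5, depth=3000, seed=3)
        assert (table.counts.sum(axis=0) == 3000).all()

    def test_rejects_non_probability_profile(self):
        with pytest.raises(ValueError):
            simulate_otu_table(2, taxa_profile=np.array([0.5, 0.2]), depth=100)

    def test_deterministic_under_seed(self):
        a = simulate_otu_table(4, depth=1000, seed=9)
        b = simulate_otu_table(4, depth=1000, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)


def test_cohort_bit_identical_under_seed():
    sim = SimConfig(seed=21)
    a, b = simulate_cohort(sim=sim), simulate_cohort(sim=sim)
    pd.testing.assert_frame_equal(a.weights, b.weights)
    pd.testing.assert_frame_equal(a.feed, b.feed)
    pd.testing.assert_frame_equal(a.otus.counts, b.otus.counts)
    for name in a.isotopes:
        assert np.array_equal(a.isotopes[name].d15n, b.isotopes[name].d15n)


def test_generator_fitter_closure(noiseless_sim):
    """The fitting module recovers the generating m from zero-noise series."""
    from compgrowth.turnover import IsotopeSeries, fit_metabolic_turnover
    from compgrowth.simulate import simulate_isotope_observations

    for k, m in [(0.051, 0.033), (0.057, 0.018), (0.061, 0.008)]:
        t, y = simulate_isotope_observations(
            8.53, 14.31, k, m, [7, 9, 14, 21, 28, 35], noise_sd=0.0
        )
        fit = fit_metabolic_turnover(IsotopeSeries("x", t, y, 8.53, 14.31), k)
        assert abs(fit.m_hat - m) <= 1e-6
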
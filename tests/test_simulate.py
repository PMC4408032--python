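"""Lifetime simulators, censoring calibration and scenario grids."""

import numpy as np
import pytest
from scipy import stats

import pgamsurv as pg
from pgamsurv import simulate as sim


class TestParametricSampling:
    def test_weibull_shape_one_is_exponential(self):
        base = pg.ParametricBaseline("weibull", 1.0, 0.25)
        u = np.array([0.2, 0.5, 0.9])
        assert np.allclose(pg.sample_parametric(base, u), -np.log(u) / 0.25)

    def test_gompertz_zero_shape_is_exponential(self):
        base = pg.ParametricBaseline("gompertz", 0.0, 0.25)
        u = np.array([0.2, 0.5, 0.9])
        assert np.allclose(pg.sample_parametric(base, u), -np.log(u) / 0.25)

    def test_weibull_empirical_cdf_matches_closed_form(self):
        base = pg.ParametricBaseline("weibull", 0.8, 0.1)
        rng = np.random.default_rng(17)
        t = pg.sample_parametric(base, rng.uniform(1e-12, 1 - 1e-12, 100_000))
        ks = stats.kstest(t, lambda x: 1.0 - base.survival(x))
        assert ks.statistic < 0.01

    def test_u_outside_unit_interval_rejected(self):
        base = pg.ParametricBaseline("weibull", 1.0, 0.1)
        with pytest.raises(ValueError):
            pg.sample_parametric(base, np.array([0.0, 0.5]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pg.ParametricBaseline("weibull", -1.0, 0.1)
        with pytest.raises(ValueError):
            pg.ParametricBaseline("lognormal", 0.0, -1.0)
        with pytest.raises(ValueError):
            pg.ParametricBaseline("gamma", 1.0, 1.0)


class TestGeneralSampling:
    def test_constant_log_hazard_closed_form(self):
        lam = 0.1
        for u in (0.2, 0.5, 0.9):
            t, flag = pg.sample_general(
                lambda x: np.full_like(np.asarray(x, float), np.log(lam)), u)
            assert not flag
            assert t == pytest.approx(-np.log(u) / lam, abs=1e-8)

    def test_baseline_a_empirical_survival_matches_numeric_truth(self):
        base = pg.GENERAL_BASELINES["A"]
        rng = np.random.default_rng(31)
        u = rng.uniform(1e-12, 1 - 1e-12, 100_000)
        t, flags = pg.sample_general(lambda x: base.log_hazard(x), u)
        assert not flags.any()
        truth = sim._NumericLifetime(lambda x: base.log_hazard(x))
        grid = np.linspace(0.05, 14.0, 120)
        emp = (t[:, None] > grid[None, :]).mean(axis=0)
        assert np.abs(emp - truth.survival(grid)).max() < 0.01

    def test_monotone_in_u(self):
        base = pg.GENERAL_BASELINES["C"]
        u = np.linspace(0.01, 0.99, 25)
        t, _ = pg.sample_general(lambda x: base.log_hazard(x), u)
        assert np.all(np.diff(t) < 0)  # u -> 1 means earlier death
        assert t[-1] < 0.25

    def test_defective_gompertz_is_administratively_censored(self):
        base = pg.ParametricBaseline("gompertz", -0.5, 0.05)
        # survival plateau: P(T = inf) = exp(-scale/|shape|) = e^{-0.1}
        t, flags = sim._sample_arm(base, None,
                                   np.linspace(0.001, 0.999, 2000))
        assert flags.any()
        assert flags.mean() == pytest.approx(np.exp(-0.1), abs=0.02)


class TestCensoringCalibration:
    def test_zero_target_needs_no_censoring(self):
        base = pg.ParametricBaseline("weibull", 1.0, 0.1)
        sc = pg.TrialScenario(n_per_arm=5, baseline=base, censoring=0.0)
        assert pg.calibrate_censoring(sc, 0.0) == 0.0

    def test_exponential_closed_form(self):
        # P(C < T) = c/(c + mu)  =>  c = target mu / (1 - target)
        mu = 0.1
        base = pg.ParametricBaseline("weibull", 1.0, mu)
        sc = pg.TrialScenario(n_per_arm=5, baseline=base, censoring=0.3)
        c = pg.calibrate_censoring(sc, 0.3)
        assert c == pytest.approx(0.3 * mu / 0.7, rel=1e-4)

    def test_weibull_rate_matches_monte_carlo(self):
        base = pg.ParametricBaseline("weibull", 0.8, 0.1)
        sc = pg.TrialScenario(n_per_arm=5, baseline=base, censoring=0.7)
        c = pg.calibrate_censoring(sc, 0.7)
        rng = np.random.default_rng(8)
        t = pg.sample_parametric(base, rng.uniform(1e-12, 1 - 1e-12, 1_000_000))
        cens = rng.exponential(1.0 / c, 1_000_000)
        assert (cens < t).mean() == pytest.approx(0.7, abs=0.005)


class TestSimulateTrial:
    def test_realized_censoring_near_target(self):
        base = pg.GENERAL_BASELINES["B"]
        sc = pg.TrialScenario(n_per_arm=5000, baseline=base,
                              deviation=pg.DeviationSpec(log_hr=np.log(0.8)),
                              censoring=0.3, seed=3)
        frame = pg.records_to_frame(pg.simulate_trial(sc))
        assert 1.0 - frame["event"].mean() == pytest.approx(0.3, abs=0.02)

    def test_null_deviation_arms_are_exchangeable(self):
        base = pg.ParametricBaseline("weibull", 1.2, 0.1)
        sc = pg.TrialScenario(n_per_arm=2000, baseline=base,
                              deviation=pg.DeviationSpec(), censoring=0.0,
                              seed=11)
        frame = pg.records_to_frame(pg.simulate_trial(sc))
        a = frame.loc[frame["arm"] == 0, "time"]
        b = frame.loc[frame["arm"] == 1, "time"]
        assert stats.ks_2samp(a, b).pvalue > 0.01

    def test_seeded_trials_are_reproducible(self):
        sc = pg.TrialScenario(n_per_arm=20, baseline=pg.GENERAL_BASELINES["D"],
                              censoring=0.3, seed=5)
        f1 = pg.records_to_frame(pg.simulate_trial(sc))
        f2 = pg.records_to_frame(pg.simulate_trial(sc))
        assert f1.equals(f2)

    def test_scenario_grids_enumerate_the_designs(self):
        assert len(pg.hr_scenario_grid()) == 48
        assert len(pg.rmst_scenario_grid()) == 32
        kinds = {k.split("|")[1] for k in pg.rmst_scenario_grid()}
        assert kinds == {"ph", "linear", "quad", "lq"}

    def test_deviation_draws_respect_their_shape(self):
        rng = np.random.default_rng(0)
        for kind, want_a, want_b in (("ph", False, False),
                                     ("linear", True, False),
                                     ("quad", False, True),
                                     ("lq", True, True)):
            dev = pg.draw_deviation(kind, rng)
            assert sim.HR_RANGE[0] <= dev.log_hr <= sim.HR_RANGE[1]
            assert (dev.a != 0.0) == want_a
            assert (dev.b != 0.0) == want_b
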
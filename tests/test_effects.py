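"""Posterior-simulation effect measures: survival, HR/RR/ARD, RMST, CGP."""

import numpy as np
import pytest

import pgamsurv as pg
from pgamsurv.effects import _survival_draws


@pytest.fixture(scope="module")
def exponential_fit():
    rng = np.random.default_rng(314)
    recs = [pg.SurvivalRecord(id=i, entry=0.0, exit=float(x), event=1)
            for i, x in enumerate(rng.exponential(10.0, 400))]
    return pg.fit_model(pg.expand(recs, 10), "s(t)")


@pytest.fixture(scope="module")
def two_arm_fit(two_arm_trial_module):
    return pg.fit_model(pg.expand(two_arm_trial_module, 10), "arm + s(t)")


@pytest.fixture(scope="module")
def two_arm_trial_module():
    base = pg.ParametricBaseline("weibull", 1.0, 0.1)
    sc = pg.TrialScenario(n_per_arm=400, baseline=base,
                          deviation=pg.DeviationSpec(log_hr=np.log(0.5)),
                          censoring=0.0)
    return pg.simulate_trial(sc, rng=np.random.default_rng(123))


class TestDrawCoefficients:
    def test_degenerate_covariance_returns_the_mean(self, exponential_fit):
        fit = exponential_fit
        saved = fit.cov.copy()
        fit.cov = np.zeros_like(fit.cov)
        draws = pg.draw_coefficients(fit, 5, seed=1)
        assert np.allclose(draws, fit.beta)
        fit.cov = saved

    def test_moments_match_the_posterior(self, exponential_fit):
        K = 100_000
        draws = pg.draw_coefficients(exponential_fit, K, seed=2)
        se = np.sqrt(np.diag(exponential_fit.cov))
        assert np.all(np.abs(draws.mean(axis=0) - exponential_fit.beta)
                      <= 4.0 * se / np.sqrt(K) + 1e-12)
        V_hat = np.cov(draws.T)
        fro = np.linalg.norm(V_hat - exponential_fit.cov)
        assert fro <= 0.05 * np.linalg.norm(exponential_fit.cov)

    def test_indefinite_covariance_rejected(self, exponential_fit):
        fit = exponential_fit
        saved = fit.cov.copy()
        fit.cov = saved - 2 * np.eye(len(fit.beta)) * np.abs(saved).max()
        with pytest.raises(ValueError):
            pg.draw_coefficients(fit, 3, seed=0)
        fit.cov = saved


class TestPredictSurvival:
    def test_survival_starts_at_one(self, exponential_fit):
        c = pg.predict_survival(exponential_fit, {}, [0.0, 5.0], K=50, seed=0)
        assert c.estimate[0] == 1.0
        assert c.lower[0] == c.upper[0] == 1.0

    def test_matches_exponential_closed_form(self, exponential_fit):
        lam = np.exp(exponential_fit.predict_log_hazard({"t": [8.0]})[0])
        times = np.array([2.0, 8.0, 15.0])
        c = pg.predict_survival(exponential_fit, {}, times, K=400, seed=3)
        assert np.allclose(c.estimate, np.exp(-0.1 * times), atol=0.05)
        assert lam == pytest.approx(0.1, abs=0.03)

    def test_draws_are_monotone_and_bounded(self, exponential_fit):
        draws = pg.draw_coefficients(exponential_fit, 40, seed=5)
        S = _survival_draws(exponential_fit, {}, np.linspace(0, 20, 30),
                            draws, 10, "t")
        assert np.all(S <= 1.0 + 1e-12) and np.all(S >= 0.0)
        assert np.all(np.diff(S, axis=1) <= 1e-12)

    def test_extrapolation_warns(self, exponential_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            pg.predict_survival(exponential_fit, {}, [1e4], K=5, seed=0)

    def test_interval_widens_with_inflated_covariance(self, exponential_fit):
        fit = exponential_fit
        c1 = pg.predict_survival(fit, {}, [5.0], K=500, seed=7)
        saved = fit.cov.copy()
        fit.cov = 9.0 * saved
        c2 = pg.predict_survival(fit, {}, [5.0], K=500, seed=7)
        fit.cov = saved
        assert (c2.upper - c2.lower)[0] > (c1.upper - c1.lower)[0]


class TestEffectCurves:
    def test_identical_configurations_are_null(self, two_arm_fit):
        out = pg.effect_curves(two_arm_fit, ({"arm": 1.0}, {"arm": 1.0}),
                               [1.0, 5.0, 10.0], K=100, seed=0)
        assert np.allclose(out["HR"].estimate, 1.0)
        assert np.allclose(out["RR"].estimate, 1.0)
        assert np.allclose(out["ARD"].estimate, 0.0, atol=1e-12)

    def test_ph_fit_gives_flat_hr_matching_coefficient(self, two_arm_fit):
        times = np.linspace(1.0, 15.0, 6)
        out = pg.effect_curves(two_arm_fit, ({"arm": 0.0}, {"arm": 1.0}),
                               times, K=2000, seed=1)
        hr = out["HR"].estimate
        assert np.ptp(hr) < 1e-6 * hr.mean()  # structurally constant in t
        a, _ = two_arm_fit.term_map["arm"]
        assert hr[0] == pytest.approx(np.exp(two_arm_fit.beta[a]), rel=0.05)
        assert hr[0] == pytest.approx(0.5, abs=0.08)

    def test_rr_tends_to_parity(self, two_arm_fit):
        out = pg.effect_curves(two_arm_fit, ({"arm": 0.0}, {"arm": 1.0}),
                               [2.0, 60.0], K=500, seed=2)
        rr = out["RR"].estimate
        assert rr[0] < rr[1] < 1.05
        assert rr[1] == pytest.approx(1.0, abs=0.1)


class TestRmst:
    def test_identical_arms_give_zero_difference(self, two_arm_fit):
        est = pg.rmst_difference(two_arm_fit, ({"arm": 1.0}, {"arm": 1.0}),
                                 10.0, K=50, seed=0)
        assert est.estimate == 0.0

    def test_exponential_closed_form(self, exponential_fit):
        # force the plug-in curve: zero covariance and an exact rate
        fit = exponential_fit
        saved_b, saved_c = fit.beta.copy(), fit.cov.copy()
        fit.beta = np.zeros_like(fit.beta)
        a, b = fit.term_map["intercept"]
        fit.beta[a] = np.log(0.1)
        fit.cov = np.zeros_like(fit.cov)
        est = pg.rmst_difference(fit, ({}, {}), 10.0, K=3, seed=0)
        r0 = est.per_arm[0]
        assert r0 == pytest.approx((1 - np.exp(-1.0)) / 0.1, abs=1e-6)
        fit.beta, fit.cov = saved_b, saved_c

    def test_rmst_bounded_by_horizon(self, two_arm_fit):
        est = pg.rmst_difference(two_arm_fit, ({"arm": 0.0}, {"arm": 1.0}),
                                 12.0, K=200, seed=4)
        assert est.per_arm[0] <= 12.0 and est.per_arm[1] <= 12.0
        assert est.lower <= est.estimate <= est.upper
        assert est.estimate > 0  # HR 0.5 favors the experimental arm


class TestCorrectedGroupPrognosis:
    def test_reduces_to_effect_curves_without_covariates(self, two_arm_fit):
        import pandas as pd
        times = [2.0, 8.0]
        cohort = pd.DataFrame({"arm": [0.0, 1.0, 0.0, 1.0]})
        cgp = pg.corrected_group_prognosis(two_arm_fit, cohort, "arm", times,
                                           K=400, seed=9)
        direct = pg.effect_curves(two_arm_fit, ({"arm": 0.0}, {"arm": 1.0}),
                                  times, K=400, seed=9)
        assert np.allclose(cgp["HR"].estimate, direct["HR"].estimate, rtol=1e-10)
        assert np.allclose(cgp["survival0"].estimate,
                           direct["survival0"].estimate, rtol=1e-10)

    def test_average_of_survivals_differs_from_survival_at_average(self):
        import pandas as pd
        rng = np.random.default_rng(21)
        # strong covariate effect: two subpopulations with distinct hazards
        z = np.repeat([0.0, 1.0], 200)
        lam = np.exp(np.log(0.05) + 2.5 * z)
        t = rng.exponential(1.0 / lam)
        recs = [pg.SurvivalRecord(id=i, entry=0.0, exit=float(x), event=1,
                                  covariates={"z": float(zi), "arm": 0.0})
                for i, (x, zi) in enumerate(zip(t, z))]
        fit = pg.fit_model(pg.expand(recs, 8), "z + s(t)")
        cohort = pd.DataFrame({"z": [0.0, 1.0], "arm": [0.0, 0.0]})
        cgp = pg.corrected_group_prognosis(fit, cohort, "arm", [10.0],
                                           K=300, seed=1)
        at_mean = pg.predict_survival(fit, {"arm": 0.0, "z": 0.5}, [10.0],
                                      K=300, seed=1)
        # Jensen gap: mean of survivals exceeds survival at the mean covariate
        assert cgp["survival0"].estimate[0] > at_mean.estimate[0] + 0.02

    def test_subgroup_filter(self, two_arm_fit):
        import pandas as pd
        cohort = pd.DataFrame({"arm": [0.0, 1.0]})
        with pytest.raises(ValueError, match="empty"):
            pg.corrected_group_prognosis(two_arm_fit, cohort, "arm", [1.0],
                                         subgroup=[False, False], K=10, seed=0)
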
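"""Design construction, penalized fitting and Wald tests."""

import numpy as np
import pytest
from lifelines import CoxPHFitter

import pgamsurv as pg
from pgamsurv.basis import CubicRegressionSpline
from pgamsurv.model import ModelSpec, build_design


def _simulate_ph_trial(seed, n_per_arm=150, log_hr=np.log(0.7), a=0.0,
                       censoring=0.3):
    base = pg.ParametricBaseline("weibull", 1.0, 0.1)
    sc = pg.TrialScenario(n_per_arm=n_per_arm, baseline=base,
                          deviation=pg.DeviationSpec(log_hr=log_hr, a=a),
                          censoring=censoring)
    rate = pg.calibrate_censoring(sc, censoring) if censoring else 0.0
    return pg.simulate_trial(sc, rng=np.random.default_rng(seed),
                             censoring_rate=rate)


class TestDesign:
    def test_intercept_only(self, exponential_records):
        ed = pg.expand(exponential_records[:10], 5)
        design = build_design(ed, ModelSpec.from_formula("1"))
        assert design.X.shape == (50, 1)
        assert np.all(design.X == 1.0)
        assert design.penalties == []

    def test_spline_penalty_null_space_is_constant_plus_linear(self):
        spl = CubicRegressionSpline(np.linspace(0, 10, 8))
        S = spl.penalty
        ev, Q = np.linalg.eigh(S)
        assert np.sum(ev < 1e-10 * ev.max()) == 2  # null-space dimension
        # constant and linear coefficient vectors are unpenalized
        assert np.abs(S @ np.ones(8)).max() < 1e-10
        assert np.abs(S @ spl.knots).max() < 1e-9
        # and a wiggly vector is penalized
        assert np.cos(spl.knots) @ S @ np.cos(spl.knots) > 1e-3

    def test_by_smooth_vanishes_at_reference_arm(self, two_arm_trial):
        ed = pg.expand(two_arm_trial, 5)
        design = build_design(ed, ModelSpec.from_formula("arm + s(t, by=arm)"))
        a, b = design.term_map["s(t,by=arm)"]
        arm0 = ed.frame["arm"].to_numpy() == 0.0
        assert np.all(design.X[arm0, a:b] == 0.0)
        assert np.any(design.X[~arm0, a:b] != 0.0)

    def test_aliased_parametric_block_rejected(self, two_arm_trial):
        for r in two_arm_trial:
            r.covariates["arm2"] = r.covariates["arm"]
        ed = pg.expand(two_arm_trial, 4)
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(ed, ModelSpec.from_formula("arm + arm2 + s(t)"))

    def test_stratum_smooths_drop_global_intercept(self, two_arm_trial):
        for i, r in enumerate(two_arm_trial):
            object.__setattr__(r, "stratum", i % 3)
        ed = pg.expand(two_arm_trial, 4)
        spec = ModelSpec.from_formula("arm + s(t, stratum=stratum, k=5)")
        assert not any(t.kind == "intercept" for t in spec.terms)
        design = build_design(ed, spec)
        # one full 5-column smooth per stratum, each with its own penalty
        a, b = design.term_map["s(t,stratum=stratum)"]
        assert b - a == 15
        assert sum(lbl.startswith("s(t,stratum") for lbl, _, _ in design.penalties) == 3

    def test_tensor_and_frailty_shapes(self, two_arm_trial):
        rng = np.random.default_rng(0)
        for r in two_arm_trial:
            r.covariates["age"] = float(rng.uniform(40, 80))
            object.__setattr__(r, "cluster", int(rng.integers(4)))
        ed = pg.expand(two_arm_trial, 4)
        design = build_design(
            ed, ModelSpec.from_formula("arm + s(t) + te(t, age, k=4) + re(cluster)"))
        a, b = design.term_map["te(t,age)"]
        assert b - a == 15  # 4*4 columns minus the sum-to-zero constraint
        assert sum(lbl.startswith("te") for lbl, _, _ in design.penalties) == 2
        a, b = design.term_map["re(cluster)"]
        assert b - a == 4


class TestFit:
    def test_intercept_fit_equals_poisson_mle(self, exponential_records):
        ed = pg.expand(exponential_records, 10)
        fit = pg.fit_model(ed, "1")
        closed = np.log(ed.d.sum() / ed.weights.sum())
        assert fit.beta[0] == pytest.approx(closed, abs=1e-10)
        assert fit.beta[0] == pytest.approx(np.log(0.1), abs=0.15)

    def test_zero_events_rejected(self):
        recs = [pg.SurvivalRecord(id=i, entry=0, exit=1.0 + i, event=0)
                for i in range(20)]
        ed = pg.expand(recs, 5)
        with pytest.raises(ValueError, match="events"):
            pg.fit_model(ed, "1")

    def test_log_hr_recovered_across_replicates(self):
        """beta_T lands within 2 SE of log 0.7 in nearly all replicates."""
        hits = 0
        reps = 50
        for rep in range(reps):
            recs = _simulate_ph_trial(1000 + rep)
            fit = pg.fit_model(pg.expand(recs, 10), "arm + s(t)")
            a, _ = fit.term_map["arm"]
            se = np.sqrt(fit.cov[a, a])
            hits += abs(fit.beta[a] - np.log(0.7)) <= 2.0 * se
        assert hits >= 44  # ~95% nominal; binomial floor at 50 replicates

    def test_matches_cox_partial_likelihood(self, two_arm_trial):
        fit = pg.fit_model(pg.expand(two_arm_trial, 10), "arm + s(t, k=12)")
        a, _ = fit.term_map["arm"]
        frame = pg.records_to_frame(two_arm_trial)
        cph = CoxPHFitter().fit(frame[["time", "event", "arm"]],
                                "time", "event")
        assert fit.beta[a] == pytest.approx(float(cph.params_["arm"]), abs=0.01)

    def test_estimate_stable_in_node_count(self, two_arm_trial):
        betas = []
        for n_nodes in (10, 20):
            fit = pg.fit_model(pg.expand(two_arm_trial, n_nodes), "arm + s(t)")
            a, _ = fit.term_map["arm"]
            betas.append(fit.beta[a])
        assert abs(betas[0] - betas[1]) < 0.005

    def test_gcv_also_converges(self, two_arm_trial):
        fit = pg.fit_model(pg.expand(two_arm_trial, 8), "arm + s(t)",
                           method="GCV")
        a, _ = fit.term_map["arm"]
        assert np.isfinite(fit.beta[a])
        assert 2.0 < fit.edf < 12.0

    def test_frailty_shrinks_cluster_effects(self, two_arm_trial):
        rng = np.random.default_rng(4)
        for r in two_arm_trial:
            object.__setattr__(r, "cluster", int(rng.integers(5)))
        ed = pg.expand(two_arm_trial, 6)
        fit = pg.fit_model(ed, "arm + s(t) + re(cluster)")
        b = fit.coef("re(cluster)")
        # null cluster effects: penalization keeps them near zero with
        # fewer effective dof than levels
        assert np.abs(b).max() < 0.5
        assert fit.edf_term["re(cluster)"] < 4.0


class TestWaldTest:
    def test_zero_block_gives_unit_pvalue(self, two_arm_trial):
        fit = pg.fit_model(pg.expand(two_arm_trial, 6), "arm + s(t)")
        fit.beta[slice(*fit.term_map["arm"])] = 0.0
        stat, df, p = pg.test_term_zero(fit, "arm")
        assert (stat, p) == (0.0, 1.0)
        with pytest.raises(KeyError):
            pg.test_term_zero(fit, "nope")

    def test_proportionality_test_type_one_error(self):
        """Under PH truth the by-smooth test rejects at roughly alpha."""
        rejections = 0
        reps = 100
        for rep in range(reps):
            recs = _simulate_ph_trial(5000 + rep)
            fit = pg.fit_model(pg.expand(recs, 8), "arm + s(t) + s(t, by=arm)")
            _, _, p = pg.test_term_zero(fit, "s(t,by=arm)")
            rejections += p < 0.05
        assert 0.0 <= rejections / reps <= 0.09

    def test_power_against_linear_deviation_exceeds_size(self):
        null_rej = power_rej = 0
        reps = 30
        for rep in range(reps):
            recs = _simulate_ph_trial(8000 + rep, a=0.1, censoring=0.0)
            fit = pg.fit_model(pg.expand(recs, 8), "arm + s(t) + s(t, by=arm)")
            _, _, p = pg.test_term_zero(fit, "s(t,by=arm)")
            power_rej += p < 0.05
            recs = _simulate_ph_trial(9000 + rep, a=0.0, censoring=0.0)
            fit = pg.fit_model(pg.expand(recs, 8), "arm + s(t) + s(t, by=arm)")
            _, _, p = pg.test_term_zero(fit, "s(t,by=arm)")
            null_rej += p < 0.05
        assert power_rej > null_rej
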
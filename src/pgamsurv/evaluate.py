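"""Performance metrics and the simulation-study harness.

Implements the standard battery for judging a survival estimator across
simulated replicates -- standardized bias, mean squared error, nominal-
coverage attainment with its binomial acceptability band, and mean
confidence-interval length -- plus a matched-pair study runner that feeds
identical datasets to every compared method (Poisson GAM, Cox partial
likelihood, Kaplan-Meier) so between-dataset variability cancels out of
the comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

from . import effects, model, simulate
from .expand import expand

__all__ = [
    "PerformanceSummary", "standardized_bias", "mse", "coverage",
    "required_replications", "run_study", "true_rmst_difference",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """One scenario x method x quantity row of a simulation study."""

    scenario: str
    method: str
    quantity: str
    std_bias_pct: float
    mse: float
    coverage: float
    acceptable: bool
    band: tuple
    cil: float
    n_ok: int
    n_fail: int


def standardized_bias(estimates, truth) -> float:
    """Bias in percent of the empirical SD of the estimates.

    ``100 * (mean(estimates) - truth) / SD(estimates)`` with the n-1
    divisor; ``truth`` may be a per-replicate vector, in which case the
    statistic is computed on the errors ``estimate - truth``.
    """
    est = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 estimates")
    err = est - truth
    sd = err.std(ddof=1) if truth.ndim else est.std(ddof=1)
    if sd == 0:
        if np.isclose(err.mean(), 0):
            return 0.0
        raise ValueError("estimates have zero spread but nonzero bias")
    return float(100.0 * err.mean() / sd)


def mse(estimates, truth) -> float:
    """Mean squared deviation of the estimates from the truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least 1 estimate")
    return float(np.mean((est - np.asarray(truth, dtype=float)) ** 2))


def coverage(intervals, truth, nominal: float = 0.95):
    """Proportion of intervals containing the truth, with acceptability.

    The band is ``nominal +/- 2 sqrt(nominal (1 - nominal) / N)``; coverage
    is acceptable when it falls inside.  ``truth`` may be per-interval.
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("intervals must be an (N, 2) array of (lo, hi)")
    if np.any(iv[:, 0] > iv[:, 1]):
        raise ValueError("found an interval with lo > hi")
    truth = np.asarray(truth, dtype=float)
    hit = (iv[:, 0] <= truth) & (truth <= iv[:, 1])
    cov = float(hit.mean())
    half = 2.0 * math.sqrt(nominal * (1.0 - nominal) / len(iv))
    band = (nominal - half, nominal + half)
    return cov, band[0] <= cov <= band[1], band


def required_replications(sigma: float, delta: float, alpha: float = 0.05) -> int:
    """Replicates needed to estimate a mean to accuracy delta:
    ``ceil((z_{1-alpha/2} sigma / delta)^2)``."""
    if sigma <= 0 or delta <= 0:
        raise ValueError("sigma and delta must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return int(math.ceil((z * sigma / delta) ** 2))


# ---------------------------------------------------------------------------
# Study harness


def true_rmst_difference(baseline, deviation, t_max: float) -> float:
    """True RMST difference by adaptive (Gauss-Kronrod) integration of the
    simulated arm survival functions over [0, t_max]."""
    s0 = simulate._arm_survival(baseline, None)
    s1 = simulate._arm_survival(baseline, deviation)
    d, _ = quad(lambda t: s1(t) - s0(t), 0.0, t_max, limit=200)
    return float(d)


def _rep_seed(master: int, scenario_idx: int, rep: int):
    return np.random.SeedSequence([int(master), int(scenario_idx), int(rep)])


def _km_at(kmf, t):
    s = float(kmf.survival_function_at_times(t).iloc[0])
    ci = kmf.confidence_interval_survival_function_
    pos = max(int(np.searchsorted(ci.index.values, t, side="right")) - 1, 0)
    return s, float(ci.iloc[pos, 0]), float(ci.iloc[pos, 1])


def _survival_replicate(scenario, kind_unused, rng, methods, K, n_nodes):
    """One single-arm replicate: S(t) at 50%/95% of max observation time."""
    from lifelines import KaplanMeierFitter

    rate = scenario.meta["rate"]
    records = simulate.simulate_trial(scenario.trial, rng=rng,
                                      censoring_rate=rate)
    records = [r for r in records if r.covariates["arm"] == 0.0]
    frame = simulate.records_to_frame(records)
    tmax = frame["time"].max()
    fit = curve_times = None
    if "pgam" in methods:
        fit = model.fit_model(expand(records, n_nodes), "s(t)")
        curve_times = [0.5 * tmax, 0.95 * tmax]
        curve = effects.predict_survival(fit, {}, curve_times, K=K,
                                         seed=int(rng.integers(2 ** 31)))
    if "km" in methods:
        kmf = KaplanMeierFitter()
        kmf.fit(frame["time"], frame["event"])
    rows = []
    for j, (frac, tag) in enumerate(((0.5, "surv@50%"), (0.95, "surv@95%"))):
        t_eval = frac * tmax
        truth = float(scenario.meta["survival"](t_eval))
        if "pgam" in methods:
            rows.append((tag, "pgam", float(curve.estimate[j]),
                         float(curve.lower[j]), float(curve.upper[j]), truth))
        if "km" in methods:
            s, lo, hi = _km_at(kmf, t_eval)
            rows.append((tag, "km", s, lo, hi, truth))
    return rows


def _hr_replicate(scenario, kind_unused, rng, methods, K, n_nodes):
    """One two-arm PH replicate: the log hazard ratio."""
    from lifelines import CoxPHFitter

    rate = scenario.meta["rate"]
    records = simulate.simulate_trial(scenario.trial, rng=rng,
                                      censoring_rate=rate)
    truth = scenario.trial.deviation.log_hr
    rows = []
    if "pgam" in methods:
        fit = model.fit_model(expand(records, n_nodes), "arm + s(t)")
        a, _ = fit.design.term_map["arm"]
        est = float(fit.beta[a])
        se = float(np.sqrt(fit.cov[a, a]))
        rows.append(("log_hr", "pgam", est, est - 1.96 * se, est + 1.96 * se,
                     truth))
    if "cox" in methods:
        cph = CoxPHFitter()
        cph.fit(simulate.records_to_frame(records)[["time", "event", "arm"]],
                duration_col="time", event_col="event")
        est = float(cph.params_["arm"])
        se = float(cph.standard_errors_["arm"])
        rows.append(("log_hr", "cox", est, est - 1.96 * se, est + 1.96 * se,
                     truth))
    return rows


def _rmst_replicate(scenario, kind, rng, methods, K, n_nodes):
    """One two-arm general-baseline replicate: RMST difference at T_max.

    Deviation parameters are redrawn per replicate; the truth comes from
    adaptive integration of the simulated hazards.
    """
    dev = simulate.draw_deviation(kind, rng)
    trial = simulate.TrialScenario(
        n_per_arm=scenario.trial.n_per_arm, baseline=scenario.trial.baseline,
        deviation=dev, censoring=scenario.trial.censoring)
    rate = simulate.calibrate_censoring(trial, trial.censoring) \
        if trial.censoring > 0 else 0.0
    records = simulate.simulate_trial(trial, rng=rng, censoring_rate=rate)
    t_max = max(r.exit for r in records)
    fit = model.fit_model(expand(records, n_nodes), "arm + s(t) + s(t, by=arm)")
    est = effects.rmst_difference(fit, ({"arm": 0.0}, {"arm": 1.0}), t_max,
                                  K=K, seed=rng.integers(2 ** 31))
    truth = true_rmst_difference(trial.baseline, dev, t_max)
    return [("rmst_diff", "pgam", est.estimate, est.lower, est.upper, truth)]


@dataclass
class StudyScenario:
    """A named scenario with its replicate runner and cached metadata."""

    name: str
    trial: simulate.TrialScenario
    kind: str  # survival | hr | rmst
    deviation_kind: str | None = None
    meta: dict = None


def make_scenarios(which: str, subset=None, n_per_arm: int = 300):
    """Build study scenarios of a given flavor.

    ``which`` is ``survival`` (single-arm baselines vs KM), ``hr``
    (two-arm proportional hazards vs Cox) or ``rmst`` (general baselines,
    deviation parameters drawn per replicate).  ``subset`` selects
    scenario names.
    """
    out = []
    if which == "survival":
        grid = {**simulate.WEIBULL_BASELINES, **simulate.GOMPERTZ_BASELINES,
                **simulate.LOGNORMAL_BASELINES}
        for name, base in grid.items():
            for cens in (0.3, 0.7):
                key = f"{name}|cens={int(cens * 100)}"
                trial = simulate.TrialScenario(
                    n_per_arm=n_per_arm, baseline=base, censoring=cens)
                out.append(StudyScenario(key, trial, "survival"))
    elif which == "hr":
        for key, trial in simulate.hr_scenario_grid(n_per_arm).items():
            out.append(StudyScenario(key, trial, "hr"))
    elif which == "rmst":
        for key, (trial, kind) in simulate.rmst_scenario_grid(n_per_arm).items():
            out.append(StudyScenario(key, trial, "rmst", deviation_kind=kind))
    else:
        raise ValueError(f"unknown study flavor {which!r}")
    if subset is not None:
        chosen = [s for s in out if s.name in set(subset)]
        missing = set(subset) - {s.name for s in chosen}
        if missing:
            raise KeyError(f"unknown scenario name(s): {sorted(missing)}")
        out = chosen
    return out


_RUNNERS = {"survival": _survival_replicate, "hr": _hr_replicate,
            "rmst": _rmst_replicate}


def run_study(scenarios, methods=("pgam",), reps: int = 100, seed: int = 0,
              K: int = 200, n_nodes: int = 10, nominal: float = 0.95):
    """Run a matched-pair simulation study.

    Every method sees the identical replicate datasets (replicate seeds
    depend only on the master seed, the scenario index and the replicate
    index, never on the method).  Replicate failures are recorded and
    excluded, never silently dropped.

    Returns ``(summary, replicates)``: the per-scenario metric table and
    the replicate-level estimates with their truths.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    rep_rows = []
    for s_idx, sc in enumerate(scenarios):
        runner = _RUNNERS[sc.kind]
        sc.meta = {}
        if sc.kind in ("survival", "hr"):
            # calibration is per scenario; reuse across replicates
            sc.meta["rate"] = simulate.calibrate_censoring(
                sc.trial, sc.trial.censoring) if sc.trial.censoring > 0 else 0.0
            if sc.kind == "survival":
                sc.meta["survival"] = simulate._arm_survival(sc.trial.baseline, None)
        n_fail = 0
        for rep in range(reps):
            rng = np.random.default_rng(_rep_seed(seed, s_idx, rep))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rows = runner(sc, sc.deviation_kind, rng, methods, K,
                                  n_nodes)
            except Exception as exc:  # noqa: BLE001 - logged, counted
                n_fail += 1
                warnings.warn(f"replicate {rep} of {sc.name} failed: {exc}",
                              stacklevel=2)
                continue
            for qty, meth, est, lo, hi, truth in rows:
                rep_rows.append({"scenario": sc.name, "kind": sc.kind,
                                 "method": meth, "quantity": qty, "rep": rep,
                                 "estimate": est, "lower": lo, "upper": hi,
                                 "truth": truth})
        sc.meta["n_fail"] = n_fail

    replicates = pd.DataFrame(rep_rows)
    summaries = []
    if len(replicates):
        for (name, meth, qty), grp in replicates.groupby(
                ["scenario", "method", "quantity"], sort=False):
            est = grp["estimate"].to_numpy()
            truth = grp["truth"].to_numpy()
            cov, ok, band = coverage(grp[["lower", "upper"]].to_numpy(),
                                     truth, nominal)
            n_fail = next(s.meta["n_fail"] for s in scenarios if s.name == name)
            summaries.append(PerformanceSummary(
                scenario=name, method=meth, quantity=qty,
                std_bias_pct=standardized_bias(est, truth),
                mse=mse(est, truth), coverage=cov, acceptable=ok, band=band,
                cil=float((grp["upper"] - grp["lower"]).mean()),
                n_ok=len(grp), n_fail=n_fail))
    summary = pd.DataFrame([s.__dict__ for s in summaries])
    return summary, replicates


def pooled_standardized_bias(replicates: pd.DataFrame, quantity: str,
                             method: str = "pgam") -> float:
    """Standardized bias pooled over scenarios at matched replicate level.

    Errors ``estimate - truth`` from all scenarios are pooled and the bias
    expressed in percent of their pooled SD -- the scaled-down analogue of
    per-scenario standardized bias when per-scenario replicate counts are
    modest.
    """
    grp = replicates[(replicates["quantity"] == quantity)
                     & (replicates["method"] == method)]
    if len(grp) < 2:
        raise ValueError("not enough replicates to pool")
    return standardized_bias(grp["estimate"].to_numpy(),
                             grp["truth"].to_numpy())
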
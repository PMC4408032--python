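"""Reduced-scale benchmark suites for the estimator's operating
characteristics.

These are the desk-scale renditions of the full simulation designs: a
four-scenario subset per study flavor, 100 matched replicates each,
chosen to span the design factors (baseline family/shape, deviation shape,
30%/70% censoring).  Besides per-scenario metrics, each suite reports a
pooled standardized bias -- errors ``estimate - truth`` pooled over the
matched replicates of all four scenarios -- whose Monte-Carlo noise at
this scale (~5 points of standardized bias) is low enough to compare
against the acceptability thresholds.
"""

from __future__ import annotations

import numpy as np

from . import evaluate, quadrature

RMST_SUBSET = ["A|ph|cens=30", "B|linear|cens=70",
               "C|quad|cens=30", "D|lq|cens=70"]
SURVIVAL_SUBSET = ["weibull(0.8/0.1)|cens=30", "gompertz(0.1/0.05)|cens=70",
                   "lognormal(0.5/1.0)|cens=30", "weibull(1.2/0.2)|cens=70"]
HR_SUBSET = ["weibull(0.8/0.1)|HR=0.7|cens=30",
             "weibull(1.2/0.2)|HR=0.9|cens=70",
             "gompertz(0.1/0.05)|HR=0.5|cens=30",
             "gompertz(-0.01/0.15)|HR=0.7|cens=70"]


def rmst_bias_suite(seed: int, reps: int = 100, n_per_arm: int = 300):
    """Non-PH PGAM RMST differences on general baselines A-D.

    Scenarios span proportional, linear, quadratic and linear-quadratic
    deviations at both censoring levels; deviation parameters are redrawn
    per replicate and the truth integrated from the simulated hazards.
    Returns ``(pooled_abs_std_bias_pct, summary, replicates)``.
    """
    scen = evaluate.make_scenarios("rmst", subset=RMST_SUBSET,
                                   n_per_arm=n_per_arm)
    summary, reps_df = evaluate.run_study(scen, methods=("pgam",), reps=reps,
                                          seed=seed, K=200)
    pooled = abs(evaluate.pooled_standardized_bias(reps_df, "rmst_diff"))
    return pooled, summary, reps_df


def survival_bias_suite(seed: int, reps: int = 100, n_per_arm: int = 300,
                        methods=("pgam", "km")):
    """Survival-probability estimates at 50%/95% of max observation time.

    Single-arm parametric baselines spanning the three families and both
    censoring levels, analyzed by the PGAM and the Kaplan-Meier estimator
    on identical datasets.  Returns ``(pooled_abs_std_bias_pct_at_midpoint,
    summary, replicates)`` for the PGAM.
    """
    scen = evaluate.make_scenarios("survival", subset=SURVIVAL_SUBSET,
                                   n_per_arm=n_per_arm)
    summary, reps_df = evaluate.run_study(scen, methods=methods, reps=reps,
                                          seed=seed, K=200)
    pooled = abs(evaluate.pooled_standardized_bias(
        reps_df[reps_df["quantity"] == "surv@50%"], "surv@50%"))
    return pooled, summary, reps_df


def hr_coverage_suite(seed: int, reps: int = 100, n_per_arm: int = 300):
    """Log-HR Wald coverage for PGAM and Cox on proportional-hazards trials.

    Returns ``(summary, replicates)``; the summary rows carry the
    coverage, its binomial acceptability band and the accept flag.
    """
    scen = evaluate.make_scenarios("hr", subset=HR_SUBSET,
                                   n_per_arm=n_per_arm)
    return evaluate.run_study(scen, methods=("pgam", "cox"), reps=reps,
                              seed=seed, K=50)


def mst_survey(n_points: int = 1000, orders=(5, 7, 10, 15, 20)):
    """The quasi-random error survey at its published scale."""
    return quadrature.survey_error(n_points, list(orders))


def survey_stats(survey) -> dict:
    return {
        "mst_mean_months": float(np.mean(survey.mst)),
        "mst_median_months": float(np.median(survey.mst)),
        "mst_min_months": float(np.min(survey.mst)),
        "mst_max_months": float(np.max(survey.mst)),
        "mean_log10_error": [float(x) for x in survey.expected_log10_error],
        "max_log10_error": [float(x) for x in survey.max_log10_error],
    }
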
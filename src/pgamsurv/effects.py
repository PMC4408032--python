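"""Simulation-based treatment-effect measures from a fitted log-hazard model.

All nonlinear functionals of the fitted log-hazard -- survival curves,
time-varying hazard ratios, relative risks, absolute risk differences and
restricted mean survival time -- are obtained the same way: draw
coefficient replicates from the Gaussian posterior ``N(psi_hat, V)``,
transform each replicate, and summarize the transformed draws by their
mean and percentile bounds.  Survival requires the cumulative hazard,
which is integrated with a dedicated Gauss-Lobatto rule per requested
time, independent of the rule used to expand the data for fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .model import FitResult, SmoothTerm, TensorTerm
from .quadrature import _canonical_lobatto

__all__ = [
    "EffectCurve", "RmstEstimate", "draw_coefficients", "predict_survival",
    "effect_curves", "rmst_difference", "corrected_group_prognosis",
]


@dataclass
class EffectCurve:
    """A time-indexed effect estimate with simulation percentile bounds."""

    measure: str  # survival | loghazard | HR | RR | ARD | RMST
    times: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    K: int
    seed: int | None = None
    arm: object = None


@dataclass
class RmstEstimate:
    """Restricted mean survival time difference with simulation CI."""

    t_max: float
    estimate: float
    lower: float
    upper: float
    per_arm: tuple
    K: int
    seed: int | None = None


def draw_coefficients(fit: FitResult, K: int, seed=None) -> np.ndarray:
    """``K`` multivariate-normal coefficient replicates from ``N(psi, V)``.

    The covariance is symmetrized and tiny negative eigenvalues are floored
    at zero; a substantially indefinite covariance raises.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    V = 0.5 * (fit.cov + fit.cov.T)
    ev, Q = linalg.eigh(V)
    top = max(ev.max(), 1e-300)
    if ev.min() < -1e-6 * top:
        raise ValueError("coefficient covariance is not positive semi-definite")
    ev = np.clip(ev, 0.0, None)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((K, len(ev)))
    return fit.beta + (z * np.sqrt(ev)) @ Q.T


def _time_variable(fit: FitResult) -> str:
    for t in fit.design.terms:
        if isinstance(t, (SmoothTerm, TensorTerm)):
            return t.var if isinstance(t, SmoothTerm) else t.var1
    raise ValueError("fit has no smooth of time; cannot integrate a hazard")


def _fitted_time_max(fit: FitResult) -> float:
    hi = -np.inf
    for t in fit.design.terms:
        if isinstance(t, SmoothTerm):
            hi = max(hi, t.knots[-1])
        elif isinstance(t, TensorTerm):
            hi = max(hi, t.knots1[-1])
    return hi


def _node_frame(fit, config, times, n_int, time_var):
    """Stacked per-time Lobatto nodes/weights and the design rows at them."""
    x, w = _canonical_lobatto(n_int)
    times = np.asarray(times, dtype=float)
    half = 0.5 * times
    nodes = (half[:, None] * (x[None, :] + 1.0)).ravel()
    wts = half[:, None] * w[None, :]
    frame = {time_var: nodes}
    for k, v in config.items():
        frame[k] = np.full(nodes.shape, v)
    R = fit.design_rows(frame)
    return R, wts


def _survival_draws(fit, config, times, draws, n_int, time_var):
    """Survival S(t) per coefficient draw: (K, n_times), S(0) = 1."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    pos = times > 0
    S = np.ones((len(draws), len(times)))
    if np.any(pos):
        R, wts = _node_frame(fit, config, times[pos], n_int, time_var)
        eta = R @ draws.T  # (n_times*n_int, K)
        h = np.exp(np.clip(eta, -700, 690))
        h = h.reshape(pos.sum(), n_int, -1)
        H = np.einsum("tn,tnk->tk", wts, h)
        S[:, pos] = np.exp(-H).T
    return S


def _summ(draws_mat):
    return (draws_mat.mean(axis=0),
            np.percentile(draws_mat, 2.5, axis=0),
            np.percentile(draws_mat, 97.5, axis=0))


def _check_extrapolation(fit, times):
    hi = _fitted_time_max(fit)
    tmax = float(np.max(times))
    if tmax > hi * (1 + 1e-9):
        warnings.warn(f"predicting at t={tmax:.4g} beyond the fitted time "
                      f"range (max knot {hi:.4g}): linear extrapolation of "
                      "the log-hazard", stacklevel=3)


def predict_survival(fit: FitResult, config: dict, times, K: int = 1000,
                     seed=None, n_int: int = 10,
                     time_var: str | None = None) -> EffectCurve:
    """Survival curve for one covariate configuration.

    Per draw ``S(t) = exp(-int_0^t h)`` with an ``n_int``-node Lobatto rule
    on ``[0, t]``; the point estimate is the draw mean and the bounds the
    2.5/97.5 percentiles.
    """
    time_var = time_var or _time_variable(fit)
    times = np.asarray(times, dtype=float)
    _check_extrapolation(fit, times)
    draws = draw_coefficients(fit, K, seed)
    S = _survival_draws(fit, config, times, draws, n_int, time_var)
    est, lo, hi = _summ(S)
    return EffectCurve("survival", times, est, lo, hi, K=K, seed=seed,
                       arm=config.get("arm"))


def effect_curves(fit: FitResult, arm_configs, times, K: int = 1000,
                  seed=None, n_int: int = 10,
                  time_var: str | None = None) -> dict:
    """HR(t), RR(t) and ARD(t) between two covariate configurations.

    ``arm_configs = (reference, experimental)``.  Per draw:
    ``HR = h1/h0``, ``RR = (1-S1)/(1-S0)``, ``ARD = (1-S1) - (1-S0)``
    (event risk, experimental minus control).  RR is undefined while no
    events have accrued under the reference arm (S0 = 1) and reported as
    NaN there.  Also returns the two survival curves from the same draws.
    """
    if len(arm_configs) != 2:
        raise ValueError("need exactly two configurations (reference first)")
    c0, c1 = arm_configs
    time_var = time_var or _time_variable(fit)
    times = np.asarray(times, dtype=float)
    _check_extrapolation(fit, times)
    draws = draw_coefficients(fit, K, seed)

    frame0 = {time_var: times, **{k: np.full(len(times), v) for k, v in c0.items()}}
    frame1 = {time_var: times, **{k: np.full(len(times), v) for k, v in c1.items()}}
    eta0 = fit.design_rows(frame0) @ draws.T
    eta1 = fit.design_rows(frame1) @ draws.T
    hr = np.exp(eta1 - eta0).T  # (K, n_times)

    S0 = _survival_draws(fit, c0, times, draws, n_int, time_var)
    S1 = _survival_draws(fit, c1, times, draws, n_int, time_var)
    risk0, risk1 = 1.0 - S0, 1.0 - S1
    undef = np.isclose(S0, 1.0).all(axis=0)
    if np.any(undef):
        warnings.warn("RR undefined where the reference arm has no event "
                      "risk yet; reported as NaN", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(risk0 > 0, risk1 / np.where(risk0 > 0, risk0, 1.0), np.nan)
    ard = risk1 - risk0

    out = {}
    for tag, mat in (("HR", hr), ("RR", rr), ("ARD", ard)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est, lo, hi = _summ(mat)
        out[tag] = EffectCurve(tag, times, est, lo, hi, K=K, seed=seed)
    e0, l0, u0 = _summ(S0)
    e1, l1, u1 = _summ(S1)
    out["survival0"] = EffectCurve("survival", times, e0, l0, u0, K=K,
                                   seed=seed, arm=0)
    out["survival1"] = EffectCurve("survival", times, e1, l1, u1, K=K,
                                   seed=seed, arm=1)
    return out


def _rmst_draws(fit, config, t_max, draws, n_int, time_var):
    x, w = _canonical_lobatto(n_int)
    half = 0.5 * t_max
    outer_t = half * (x + 1.0)
    outer_w = half * w
    S = _survival_draws(fit, config, outer_t, draws, n_int, time_var)
    return S @ outer_w  # (K,)


def rmst_difference(fit: FitResult, arm_configs, t_max: float, K: int = 1000,
                    seed=None, n_int: int = 10,
                    time_var: str | None = None) -> RmstEstimate:
    """RMST difference (experimental minus control) over ``[0, t_max]``.

    Per draw, each arm's RMST is the ``n_int``-node Lobatto integral of its
    survival curve; the difference is summarized over draws by mean and
    percentile bounds.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    if len(arm_configs) != 2:
        raise ValueError("need exactly two configurations (reference first)")
    time_var = time_var or _time_variable(fit)
    _check_extrapolation(fit, [t_max])
    draws = draw_coefficients(fit, K, seed)
    r0 = _rmst_draws(fit, arm_configs[0], t_max, draws, n_int, time_var)
    r1 = _rmst_draws(fit, arm_configs[1], t_max, draws, n_int, time_var)
    diff = r1 - r0
    return RmstEstimate(
        t_max=float(t_max), estimate=float(diff.mean()),
        lower=float(np.percentile(diff, 2.5)),
        upper=float(np.percentile(diff, 97.5)),
        per_arm=(float(r0.mean()), float(r1.mean())), K=K, seed=seed)


def corrected_group_prognosis(fit: FitResult, cohort, arm_var: str, times,
                              subgroup=None, K: int = 1000, seed=None,
                              n_int: int = 10,
                              time_var: str | None = None) -> dict:
    """Population-averaged (directly adjusted) effect curves.

    Every cohort member is pushed through the model under both
    counterfactual arm assignments; survival and hazard are averaged over
    the (optionally filtered) cohort within each arm *before* ratios or
    differences are formed.  ``cohort`` is a DataFrame of covariates;
    ``subgroup`` an optional boolean mask aligned with it.
    """
    import pandas as pd

    time_var = time_var or _time_variable(fit)
    cohort = pd.DataFrame(cohort).reset_index(drop=True)
    if subgroup is not None:
        cohort = cohort.loc[np.asarray(subgroup)].reset_index(drop=True)
    if len(cohort) == 0:
        raise ValueError("subgroup filter left an empty cohort")
    times = np.asarray(times, dtype=float)
    _check_extrapolation(fit, times)
    draws = draw_coefficients(fit, K, seed)

    Sbar, hbar = {}, {}
    for arm in (0, 1):
        S_acc = np.zeros((K, len(times)))
        h_acc = np.zeros((K, len(times)))
        for _, row in cohort.iterrows():
            config = {k: row[k] for k in cohort.columns if k != arm_var}
            config[arm_var] = arm
            S_acc += _survival_draws(fit, config, times, draws, n_int, time_var)
            frame = {time_var: times,
                     **{k: np.full(len(times), v) for k, v in config.items()}}
            h_acc += np.exp(np.clip(fit.design_rows(frame) @ draws.T, -700, 690)).T
        Sbar[arm] = S_acc / len(cohort)
        hbar[arm] = h_acc / len(cohort)

    hr = hbar[1] / hbar[0]
    risk0, risk1 = 1.0 - Sbar[0], 1.0 - Sbar[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(risk0 > 0, risk1 / np.where(risk0 > 0, risk0, 1.0), np.nan)
    ard = risk1 - risk0
    out = {}
    for tag, mat in (("HR", hr), ("RR", rr), ("ARD", ard)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est, lo, hi = _summ(mat)
        out[tag] = EffectCurve(tag, times, est, lo, hi, K=K, seed=seed)
    for arm in (0, 1):
        est, lo, hi = _summ(Sbar[arm])
        out[f"survival{arm}"] = EffectCurve("survival", times, est, lo, hi,
                                            K=K, seed=seed, arm=arm)
    return out
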
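"""Simulators for censored two-arm trial data.

Covers the full simulation design used to benchmark the Poisson-GAM
estimator: Weibull, Gompertz and Lognormal parametric baselines on the
printed parameter grids; "general" baselines defined only through a
quadratic log-hazard (sampled by the inverse-cumulative-hazard method of
Bender, Augustin and Blettner); proportional, linear, quadratic and
linear-quadratic log-hazard deviations between arms; and independent
exponential censoring whose rate is calibrated numerically to hit a
target censoring fraction.  Time is in months throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import cumulative_simpson, quad
from scipy.optimize import brentq

from .expand import SurvivalRecord

__all__ = [
    "ParametricBaseline", "GeneralBaseline", "DeviationSpec", "TrialScenario",
    "sample_parametric", "sample_general", "calibrate_censoring",
    "simulate_trial", "draw_deviation", "records_to_frame",
    "WEIBULL_BASELINES", "GOMPERTZ_BASELINES", "LOGNORMAL_BASELINES",
    "GENERAL_BASELINES", "hr_scenario_grid", "rmst_scenario_grid",
    "HR_RANGE", "LINEAR_RANGE", "QUAD_RANGE",
]

# Per-dataset deviation parameter domains for the RMST design:
# (log HR, linear, quadratic) drawn uniformly from these ranges.
HR_RANGE = (np.log(0.7), np.log(0.9))
LINEAR_RANGE = (-0.1, 0.1)
QUAD_RANGE = (-0.009, 0.009)

_HORIZON = 1000.0  # administrative-censoring horizon for defective lifetimes


@dataclass(frozen=True)
class ParametricBaseline:
    """Weibull, Gompertz or Lognormal lifetime baseline.

    Parameterizations (proportional-hazards/simulation conventions):

    * Weibull ``(shape, scale)``: ``h(t) = scale * shape * t^(shape-1)``,
      so ``H(t) = scale * t^shape``; ``shape = 1`` is exponential(scale).
    * Gompertz ``(shape, scale)``: ``h(t) = scale * exp(shape * t)``;
      ``shape -> 0`` recovers exponential(scale); negative shape gives a
      defective distribution (bounded cumulative hazard).
    * Lognormal ``(meanlog, sdlog)`` of ``log T``.
    """

    family: str
    shape: float
    scale: float

    def __post_init__(self):
        if self.family not in ("weibull", "gompertz", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "weibull" and (self.shape <= 0 or self.scale <= 0):
            raise ValueError("Weibull needs shape > 0 and scale > 0")
        if self.family == "lognormal" and self.scale <= 0:
            raise ValueError("Lognormal needs sdlog > 0")

    # (meanlog, sdlog) are stored as (shape, scale) for the lognormal
    def survival(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "weibull":
            return np.exp(-self.scale * t ** self.shape)
        if self.family == "gompertz":
            if self.shape == 0:
                return np.exp(-self.scale * t)
            with np.errstate(over="ignore"):
                H = self.scale / self.shape * (np.exp(self.shape * t) - 1.0)
            return np.exp(-np.minimum(H, 745.0))
        return stats.lognorm.sf(t, s=self.scale, scale=np.exp(self.shape))

    def cum_hazard(self, t):
        with np.errstate(divide="ignore"):
            return -np.log(self.survival(t))

    def inverse_survival(self, u):
        """Lifetime with ``S(T) = u`` (inverse-CDF sampling)."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("u must lie strictly in (0, 1)")
        neglogu = -np.log(u)
        if self.family == "weibull":
            return (neglogu / self.scale) ** (1.0 / self.shape)
        if self.family == "gompertz":
            if self.shape == 0:
                return neglogu / self.scale
            arg = 1.0 + self.shape * neglogu / self.scale
            out = np.full(u.shape, np.inf)
            ok = arg > 0
            out[ok] = np.log(arg[ok]) / self.shape
            return out
        return np.exp(self.shape + self.scale * stats.norm.ppf(1.0 - u))


@dataclass(frozen=True)
class GeneralBaseline:
    """Lifetime defined through ``log h0(t) = k0 + k1 t + k2 t^2``."""

    k0: float
    k1: float
    k2: float
    label: str = ""

    @property
    def coeffs(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2])

    def log_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return self.k0 + t * (self.k1 + t * self.k2)


@dataclass(frozen=True)
class DeviationSpec:
    """Arm log-hazard = baseline log-hazard + logHR + a t + b t^2.

    ``(a, b) = (0, 0)`` is proportional hazards.
    """

    log_hr: float = 0.0
    a: float = 0.0
    b: float = 0.0

    @property
    def proportional(self) -> bool:
        return self.a == 0.0 and self.b == 0.0


def draw_deviation(kind: str, rng) -> DeviationSpec:
    """Draw (log HR, a, b) uniformly for a named deviation shape.

    ``kind`` is one of ``ph``, ``linear``, ``quad``, ``lq``; parameters
    absent from the shape are zero.
    """
    kind = kind.lower()
    if kind not in ("ph", "linear", "quad", "lq"):
        raise ValueError(f"unknown deviation kind {kind!r}")
    log_hr = rng.uniform(*HR_RANGE)
    a = rng.uniform(*LINEAR_RANGE) if kind in ("linear", "lq") else 0.0
    b = rng.uniform(*QUAD_RANGE) if kind in ("quad", "lq") else 0.0
    return DeviationSpec(log_hr=log_hr, a=a, b=b)


@dataclass(frozen=True)
class TrialScenario:
    """A two-arm trial design: who is simulated and how they are censored."""

    n_per_arm: int
    baseline: object  # ParametricBaseline | GeneralBaseline
    deviation: DeviationSpec = field(default_factory=DeviationSpec)
    censoring: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if not 0.0 <= self.censoring < 1.0:
            raise ValueError("censoring fraction must be in [0, 1)")


def sample_parametric(baseline: ParametricBaseline, u) -> np.ndarray:
    """Inverse-CDF lifetimes from a parametric baseline (vectorized in u)."""
    return baseline.inverse_survival(np.asarray(u, dtype=float))


class _NumericLifetime:
    """Grid-based cumulative hazard with accurate inversion.

    Used for any arm whose log-hazard is a polynomial with no closed-form
    cumulative hazard (the Bender-Augustin-Blettner sampler): H is tabulated
    by cumulative Simpson on a fine uniform grid extended until it covers
    the requested quantiles, and inversion is refined by Newton steps with
    a local 7-point Lobatto correction of the tabulated H.
    """

    def __init__(self, loghazard, horizon: float = _HORIZON, n_grid: int = 8193):
        self.loghazard = loghazard
        self.horizon = float(horizon)
        self.n_grid = int(n_grid)
        self._build(16.0)

    def _build(self, t_max):
        t = np.linspace(0.0, t_max, self.n_grid)
        h = np.exp(np.clip(self.loghazard(t), -745, 700))
        H = np.concatenate([[0.0], cumulative_simpson(h, x=t)])
        self.t_grid, self.h_grid, self.H_grid = t, h, H

    def _extend_to(self, H_target):
        while self.H_grid[-1] < H_target and self.t_grid[-1] < self.horizon:
            self._build(min(2.0 * self.t_grid[-1], self.horizon))

    def cum_hazard(self, t):
        t = np.asarray(t, dtype=float)
        return np.interp(t, self.t_grid, self.H_grid)

    def survival(self, t):
        return np.exp(-np.clip(self.cum_hazard(t), 0, 700))

    def invert(self, targets, tol: float = 1e-8):
        """Solve H(t) = target; (times, administratively_censored flags)."""
        targets = np.atleast_1d(np.asarray(targets, dtype=float))
        self._extend_to(targets.max() * 1.05 + 1.0)
        censored = targets > self.H_grid[-1]
        tt = np.minimum(targets, self.H_grid[-1])
        t = np.interp(tt, self.H_grid, self.t_grid)
        # Newton refinement with locally re-integrated H
        from .quadrature import _canonical_lobatto
        x7, w7 = _canonical_lobatto(7)
        idx = np.clip(np.searchsorted(self.t_grid, t) - 1, 0, self.n_grid - 2)
        for _ in range(4):
            t0 = self.t_grid[idx]
            half = 0.5 * (t - t0)
            nodes = t0[:, None] + half[:, None] * (x7[None, :] + 1.0)
            hv = np.exp(np.clip(self.loghazard(nodes), -745, 700))
            H_loc = self.H_grid[idx] + (hv @ w7) * half
            ht = np.exp(np.clip(self.loghazard(t), -745, 700))
            step = (H_loc - tt) / np.maximum(ht, 1e-300)
            t = np.clip(t - step, self.t_grid[idx], None)
            if np.max(np.abs(step)) < tol * np.maximum(1.0, np.max(t)):
                break
        t[censored] = self.t_grid[-1]
        return t, censored


def sample_general(loghazard, u, horizon: float = _HORIZON, tol: float = 1e-8):
    """Lifetimes from a general hazard via inverse cumulative-hazard sampling.

    ``loghazard`` is a vectorized callable of time; ``u`` uniform variates
    in (0, 1) with ``H(T) = -log u``.  Lifetimes whose target cumulative
    hazard is unreachable inside ``horizon`` are administratively censored
    there and flagged.  Returns ``(times, censored_flags)``; pass a scalar
    ``u`` to get scalars back.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any((u_arr <= 0) | (u_arr >= 1)):
        raise ValueError("u must lie strictly in (0, 1)")
    inv = _NumericLifetime(loghazard, horizon=horizon)
    t, flag = inv.invert(-np.log(u_arr), tol=tol)
    if np.isscalar(u) or np.ndim(u) == 0:
        return float(t[0]), bool(flag[0])
    return t, flag


def _arm_survival(baseline, deviation: DeviationSpec | None, horizon=_HORIZON):
    """Survival callable for (baseline, deviation); None = control arm."""
    if deviation is None:
        deviation = DeviationSpec()
    if isinstance(baseline, ParametricBaseline) and deviation.proportional:
        hr = np.exp(deviation.log_hr)
        return lambda t: baseline.survival(t) ** hr if hr != 1.0 else baseline.survival(t)
    if isinstance(baseline, ParametricBaseline):
        # numeric: h(t) = h0(t) exp(logHR + a t + b t^2); h0 needs care at 0
        def loghazard(t):
            t = np.asarray(t, dtype=float)
            if baseline.family == "weibull":
                with np.errstate(divide="ignore"):
                    lh0 = (np.log(baseline.scale * baseline.shape)
                           + (baseline.shape - 1.0) * np.log(np.maximum(t, 1e-300)))
            elif baseline.family == "gompertz":
                lh0 = np.log(baseline.scale) + baseline.shape * t
            else:
                tt = np.maximum(t, 1e-300)
                pdf = stats.lognorm.pdf(tt, s=baseline.scale,
                                        scale=np.exp(baseline.shape))
                sf = stats.lognorm.sf(tt, s=baseline.scale,
                                      scale=np.exp(baseline.shape))
                with np.errstate(divide="ignore"):
                    lh0 = np.log(pdf) - np.log(sf)
            return lh0 + deviation.log_hr + t * (deviation.a + t * deviation.b)
        return _NumericLifetime(loghazard, horizon=horizon).survival
    coeffs = baseline.coeffs + np.array([deviation.log_hr, deviation.a, deviation.b])

    def loghazard(t):
        t = np.asarray(t, dtype=float)
        return coeffs[0] + t * (coeffs[1] + t * coeffs[2])

    return _NumericLifetime(loghazard, horizon=horizon).survival


def _sample_arm(baseline, deviation, u, horizon=_HORIZON):
    """Lifetimes for one arm; returns (times, administratively_censored)."""
    if isinstance(baseline, ParametricBaseline) and (
            deviation is None or deviation.proportional):
        hr = 1.0 if deviation is None else np.exp(deviation.log_hr)
        t = baseline.inverse_survival(np.asarray(u) ** (1.0 / hr))
        flag = ~np.isfinite(t)
        t = np.where(flag, horizon, t)
        return t, flag
    if isinstance(baseline, ParametricBaseline):
        surv = _arm_survival(baseline, deviation, horizon)
        inv = surv.__self__  # the _NumericLifetime instance
        return inv.invert(-np.log(np.asarray(u, dtype=float)))
    coeffs = baseline.coeffs.copy()
    if deviation is not None:
        coeffs += np.array([deviation.log_hr, deviation.a, deviation.b])

    def loghazard(t):
        t = np.asarray(t, dtype=float)
        return coeffs[0] + t * (coeffs[1] + t * coeffs[2])

    return sample_general(loghazard, np.asarray(u, dtype=float), horizon=horizon)


def calibrate_censoring(scenario_or_survival, target: float,
                        tol: float = 1e-6) -> float:
    """Exponential censoring rate hitting a target censoring fraction.

    Solves ``P(C < T) = target`` for ``C ~ Exp(rate)`` where ``T`` follows
    the trial's lifetime law -- for a :class:`TrialScenario`, the equal-
    allocation two-arm mixture.  ``P(C < T) = int c e^{-ct} S_T(t) dt`` is
    evaluated by adaptive quadrature and the rate located by root finding.
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target censoring fraction must be in [0, 1)")
    if target == 0.0:
        return 0.0
    if isinstance(scenario_or_survival, TrialScenario):
        sc = scenario_or_survival
        s0 = _arm_survival(sc.baseline, None)
        s1 = _arm_survival(sc.baseline, sc.deviation)
        surv = lambda t: 0.5 * (s0(t) + s1(t))
    else:
        surv = scenario_or_survival

    def frac(log_c):
        # P(C < T) = int_0^1 S_T(-log(1-u)/c) du  (u = 1 - e^{-ct})
        c = np.exp(log_c)
        val, _ = quad(lambda u: float(surv(-np.log1p(-u) / c)), 0.0, 1.0,
                      limit=200)
        return val - target

    lo, hi = -20.0, 15.0
    flo, fhi = frac(lo), frac(hi)
    if flo > 0 or fhi < 0:
        raise ValueError(
            f"no censoring rate in [e^{lo}, e^{hi}] reaches target {target} "
            f"(P at bracket ends: {flo + target:.4f}, {fhi + target:.4f})")
    return float(np.exp(brentq(frac, lo, hi, xtol=tol, rtol=tol)))


def simulate_trial(scenario: TrialScenario, rng=None,
                   censoring_rate: float | None = None):
    """Simulate one two-arm censored trial.

    Lifetimes come from each arm's hazard; censoring is independent
    exponential at the calibrated rate (pass ``censoring_rate`` to reuse a
    calibration across replicates); ``F = min(T, C)``, ``event = T <= C``.
    Returns a list of :class:`SurvivalRecord` with covariate ``arm``.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    if censoring_rate is None:
        censoring_rate = calibrate_censoring(scenario, scenario.censoring) \
            if scenario.censoring > 0 else 0.0
    n = scenario.n_per_arm
    records = []
    for arm, deviation in ((0, None), (1, scenario.deviation)):
        u = rng.uniform(size=n)
        u = np.clip(u, 1e-15, 1.0 - 1e-15)
        t, admin = _sample_arm(scenario.baseline, deviation, u)
        c = rng.exponential(1.0 / censoring_rate, size=n) \
            if censoring_rate > 0 else np.full(n, np.inf)
        f = np.minimum(t, c)
        delta = ((t <= c) & ~admin).astype(int)
        for i in range(n):
            records.append(SurvivalRecord(
                id=f"a{arm}_{i}", entry=0.0, exit=float(f[i]),
                event=int(delta[i]), covariates={"arm": float(arm)}))
    return records


def records_to_frame(records):
    """Subject-level DataFrame (id, entry, time, event, covariates)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"id": r.id, "entry": r.entry, "time": r.exit, "event": r.event}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Printed parameter grids, packaged as named fixtures.

WEIBULL_BASELINES = {
    f"weibull({s}/{sc})": ParametricBaseline("weibull", s, sc)
    for s, sc in [(0.8, 0.1), (1.2, 0.1), (0.8, 0.2), (1.2, 0.2)]
}
GOMPERTZ_BASELINES = {
    f"gompertz({s}/{sc})": ParametricBaseline("gompertz", s, sc)
    for s, sc in [(-0.01, 0.05), (0.1, 0.05), (-0.01, 0.15), (0.1, 0.15)]
}
LOGNORMAL_BASELINES = {
    f"lognormal({m}/{s})": ParametricBaseline("lognormal", m, s)
    for m, s in [(0.5, 1.0), (1.0, 1.0), (1.5, 1.8), (1.5, 0.8)]
}
GENERAL_BASELINES = {
    "A": GeneralBaseline(np.log(0.05), 0.20, 0.02, "A"),
    "B": GeneralBaseline(np.log(0.10), -0.10, 0.02, "B"),
    "C": GeneralBaseline(np.log(0.05), -0.02, 0.02, "C"),
    "D": GeneralBaseline(np.log(0.10), 0.10, 0.01, "D"),
}


def hr_scenario_grid(n_per_arm: int = 300):
    """The 48 hazard-ratio scenarios: {Weibull, Gompertz} x 4 baselines x
    HR in {0.5, 0.7, 0.9} x censoring in {30%, 70%}."""
    out = {}
    for name, base in {**WEIBULL_BASELINES, **GOMPERTZ_BASELINES}.items():
        for hr in (0.5, 0.7, 0.9):
            for cens in (0.3, 0.7):
                key = f"{name}|HR={hr}|cens={int(cens * 100)}"
                out[key] = TrialScenario(
                    n_per_arm=n_per_arm, baseline=base,
                    deviation=DeviationSpec(log_hr=np.log(hr)), censoring=cens)
    return out


def rmst_scenario_grid(n_per_arm: int = 300):
    """The 32 RMST scenarios: baselines A-D x deviation shape x censoring.

    Deviation parameters are drawn per replicate (see
    :func:`draw_deviation`); the grid entries carry the shape name.
    """
    out = {}
    for name, base in GENERAL_BASELINES.items():
        for kind in ("ph", "linear", "quad", "lq"):
            for cens in (0.3, 0.7):
                key = f"{name}|{kind}|cens={int(cens * 100)}"
                out[key] = (TrialScenario(n_per_arm=n_per_arm, baseline=base,
                                          censoring=cens), kind)
    return out
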
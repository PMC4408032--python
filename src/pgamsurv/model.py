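"""Penalized Poisson GAM for the log-hazard of expanded survival data.

The log-hazard of the ``i``-th subject at node time ``t`` is resolved as a
sum of model terms:

* parametric covariate effects (log-hazard ratios),
* penalized spline smooths of study time -- the baseline log-hazard,
  optionally one full smooth per stratum,
* "by"-variable smooths giving a covariate a time-varying coefficient
  (the non-proportionality component of a treatment effect),
* tensor-product smooths over pairs of time scales, and
* Gaussian frailty (random-effect) columns over cluster labels.

Coefficients are estimated by penalized iteratively reweighted least
squares (PIRLS) on the Poisson pseudo-likelihood with log-weight offsets;
smoothing parameters are chosen by REML (Laplace-approximate marginal
likelihood of the mixed-model representation) or GCV.  The posterior
covariance ``V = (X'WX + S_lambda)^{-1}`` drives all downstream
simulation-based inference.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize

from .basis import CubicRegressionSpline, quantile_knots, sum_to_zero_constraint
from .expand import ExpandedData

__all__ = [
    "ModelSpec", "FitResult", "build_design", "fit", "fit_model",
    "test_term_zero", "load_fit",
    "LinearTerm", "SmoothTerm", "TensorTerm", "RandomEffectTerm",
]

_EIG_TOL = 1e-10


def _get(frame, name):
    arr = np.asarray(frame[name], dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"column {name!r} contains non-finite values")
    return arr


class LinearTerm:
    """A covariate entering the log-hazard linearly (a log-hazard ratio)."""

    kind = "linear"

    def __init__(self, var: str):
        self.var = var
        self.name = var

    def build(self, frame):
        return _get(frame, self.var)[:, None], []

    def rows(self, frame):
        return _get(frame, self.var)[:, None]

    def state(self):
        return {"kind": self.kind, "var": self.var}


class InterceptTerm:
    kind = "intercept"
    name = "intercept"

    def build(self, frame):
        n = len(frame[next(iter(frame.keys()))]) if isinstance(frame, dict) else len(frame)
        return np.ones((n, 1)), []

    def rows(self, frame):
        return self.build(frame)[0]

    def state(self):
        return {"kind": self.kind}


class SmoothTerm:
    """Penalized cubic-regression-spline smooth of one variable.

    ``by`` multiplies the (centered) basis by a numeric covariate, giving
    that covariate a smooth time-varying coefficient.  ``stratum`` replaces
    the single smooth with one full (uncentered) smooth per stratum level;
    the model then drops its global intercept.
    """

    kind = "smooth"

    def __init__(self, var: str, k: int = 8, by: str | None = None,
                 stratum: str | None = None):
        if by is not None and stratum is not None:
            raise ValueError("a smooth cannot have both 'by' and 'stratum'")
        self.var, self.k, self.by, self.stratum = var, int(k), by, stratum
        self.name = (f"s({var})" if by is None and stratum is None
                     else f"s({var},by={by})" if by is not None
                     else f"s({var},stratum={stratum})")
        self.knots = None
        self.Z = None
        self.levels = None

    def _spline(self):
        return CubicRegressionSpline(self.knots)

    def build(self, frame):
        x = _get(frame, self.var)
        self.knots = quantile_knots(x, self.k)
        spl = self._spline()
        X0 = spl.design(x)
        if self.stratum is not None:
            lev = np.asarray(frame[self.stratum])
            self.levels = sorted(set(lev.tolist()))
            cols, pens = [], []
            for lv in self.levels:
                m = (lev == lv).astype(float)
                cols.append(X0 * m[:, None])
                pens.append(spl.penalty)
            return np.hstack(cols), pens
        self.Z = sum_to_zero_constraint(X0)
        Xc = X0 @ self.Z
        S = self.Z.T @ spl.penalty @ self.Z
        if self.by is not None:
            Xc = Xc * _get(frame, self.by)[:, None]
        return Xc, [S]

    def rows(self, frame):
        spl = self._spline()
        X0 = spl.design(_get(frame, self.var))
        if self.stratum is not None:
            lev = np.asarray(frame[self.stratum])
            unknown = set(lev.tolist()) - set(self.levels)
            if unknown:
                raise ValueError(f"unknown stratum level(s): {sorted(unknown)}")
            cols = [X0 * (lev == lv).astype(float)[:, None] for lv in self.levels]
            return np.hstack(cols)
        Xc = X0 @ self.Z
        if self.by is not None:
            Xc = Xc * _get(frame, self.by)[:, None]
        return Xc

    def state(self):
        return {"kind": self.kind, "var": self.var, "k": self.k,
                "by": self.by, "stratum": self.stratum,
                "knots": self.knots.tolist(),
                "Z": None if self.Z is None else self.Z.tolist(),
                "levels": self.levels}


class TensorTerm:
    """Tensor-product smooth over two time scales.

    Row-wise product of two marginal cubic-regression bases, sum-to-zero
    constrained, with one wiggliness penalty per margin.
    """

    kind = "tensor"

    def __init__(self, var1: str, var2: str, k1: int = 5, k2: int = 5):
        self.var1, self.var2, self.k1, self.k2 = var1, var2, int(k1), int(k2)
        self.name = f"te({var1},{var2})"
        self.knots1 = self.knots2 = self.Z = None

    def _marginal(self, frame, learn):
        x1, x2 = _get(frame, self.var1), _get(frame, self.var2)
        if learn:
            self.knots1 = quantile_knots(x1, self.k1)
            self.knots2 = quantile_knots(x2, self.k2)
        s1 = CubicRegressionSpline(self.knots1)
        s2 = CubicRegressionSpline(self.knots2)
        X1, X2 = s1.design(x1), s2.design(x2)
        X = X1[:, :, None] * X2[:, None, :]
        return X.reshape(len(X1), -1), s1, s2

    def build(self, frame):
        X, s1, s2 = self._marginal(frame, learn=True)
        self.Z = sum_to_zero_constraint(X)
        Xc = X @ self.Z
        I1, I2 = np.eye(s1.n_basis), np.eye(s2.n_basis)
        Sa = np.kron(s1.penalty, I2)
        Sb = np.kron(I1, s2.penalty)
        return Xc, [self.Z.T @ Sa @ self.Z, self.Z.T @ Sb @ self.Z]

    def rows(self, frame):
        X, _, _ = self._marginal(frame, learn=False)
        return X @ self.Z

    def state(self):
        return {"kind": self.kind, "var1": self.var1, "var2": self.var2,
                "k1": self.k1, "k2": self.k2,
                "knots1": self.knots1.tolist(), "knots2": self.knots2.tolist(),
                "Z": self.Z.tolist()}


class RandomEffectTerm:
    """Gaussian frailty: one penalized coefficient per cluster level.

    The identity penalty is the implied precision of iid N(0, sigma^2)
    effects; the smoothing parameter plays the role of 1/sigma^2.
    """

    kind = "random"

    def __init__(self, var: str):
        self.var = var
        self.name = f"re({var})"
        self.levels = None

    def build(self, frame):
        lev = np.asarray(frame[self.var])
        self.levels = sorted(set(lev.tolist()))
        X = np.column_stack([(lev == lv).astype(float) for lv in self.levels])
        return X, [np.eye(len(self.levels))]

    def rows(self, frame):
        lev = np.asarray(frame[self.var])
        # unseen levels predict at the population mean (all-zero row)
        return np.column_stack([(lev == lv).astype(float) for lv in self.levels])

    def state(self):
        return {"kind": self.kind, "var": self.var, "levels": self.levels}


def _term_from_state(st: dict):
    kind = st["kind"]
    if kind == "intercept":
        return InterceptTerm()
    if kind == "linear":
        return LinearTerm(st["var"])
    if kind == "smooth":
        t = SmoothTerm(st["var"], st["k"], st["by"], st["stratum"])
        t.knots = np.asarray(st["knots"])
        t.Z = None if st["Z"] is None else np.asarray(st["Z"])
        t.levels = st["levels"]
        return t
    if kind == "tensor":
        t = TensorTerm(st["var1"], st["var2"], st["k1"], st["k2"])
        t.knots1 = np.asarray(st["knots1"])
        t.knots2 = np.asarray(st["knots2"])
        t.Z = np.asarray(st["Z"])
        return t
    if kind == "random":
        t = RandomEffectTerm(st["var"])
        t.levels = st["levels"]
        return t
    raise ValueError(f"unknown term kind {kind!r}")


_CALL_RE = re.compile(r"^(s|te|re)\((.*)\)$")


def _parse_token(tok: str):
    tok = tok.strip()
    if tok == "1":
        return InterceptTerm()
    m = _CALL_RE.match(tok)
    if m is None:
        if not re.match(r"^[A-Za-z_][A-Za-z0-9_.]*$", tok):
            raise ValueError(f"cannot parse model term {tok!r}")
        return LinearTerm(tok)
    fn, args = m.group(1), [a.strip() for a in m.group(2).split(",") if a.strip()]
    pos, kw = [], {}
    for a in args:
        if "=" in a:
            key, val = (s.strip() for s in a.split("=", 1))
            kw[key] = int(val) if val.isdigit() else val
        else:
            pos.append(a)
    if fn == "s":
        if len(pos) != 1:
            raise ValueError(f"s() takes one variable, got {pos}")
        return SmoothTerm(pos[0], k=kw.pop("k", 8), by=kw.pop("by", None),
                          stratum=kw.pop("stratum", None))
    if fn == "te":
        if len(pos) != 2:
            raise ValueError(f"te() takes two variables, got {pos}")
        return TensorTerm(pos[0], pos[1], k1=kw.pop("k1", kw.get("k", 5)),
                          k2=kw.pop("k2", kw.pop("k", 5)))
    if len(pos) != 1:
        raise ValueError(f"re() takes one variable, got {pos}")
    return RandomEffectTerm(pos[0])


@dataclass
class ModelSpec:
    """Ordered collection of log-hazard model terms."""

    terms: list
    formula: str | None = None

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse a compact formula such as ``"arm + s(t) + s(t, by=arm)"``.

        Grammar: terms joined by ``+``; each is a bare (numeric) column
        name, ``1`` (explicit intercept), ``s(var[, k=8][, by=z][,
        stratum=g])``, ``te(v1, v2[, k=5])`` or ``re(cluster)``.  An
        intercept is added automatically unless a stratum smooth is
        present.
        """
        toks = [t for t in formula.split("+") if t.strip()]
        if not toks:
            raise ValueError("empty formula")
        terms = [_parse_token(t) for t in toks]
        has_strata = any(getattr(t, "stratum", None) is not None for t in terms)
        if not has_strata and not any(t.kind == "intercept" for t in terms):
            terms.insert(0, InterceptTerm())
        return cls(terms=terms, formula=formula)

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelSpec":
        if "formula" in cfg:
            return cls.from_formula(cfg["formula"])
        return cls(terms=[_term_from_state(s) for s in cfg["terms"]])


@dataclass
class Design:
    """Built design matrix with penalty blocks and the term/column map."""

    X: np.ndarray
    penalties: list  # (label, column indices, S block)
    term_map: dict  # term name -> (start, stop) columns
    terms: list
    spec: ModelSpec

    def rows(self, frame) -> np.ndarray:
        return np.hstack([t.rows(frame) for t in self.terms])


def build_design(expanded, spec: ModelSpec) -> Design:
    """Evaluate every model term on the expanded data.

    ``expanded`` may be an :class:`ExpandedData` or any DataFrame with the
    referenced columns.  Raises when the parametric block is rank
    deficient, naming the aliased columns.
    """
    frame = expanded.frame if isinstance(expanded, ExpandedData) else expanded
    if len(frame) == 0:
        raise ValueError("empty data")
    blocks, penalties, term_map = [], [], {}
    col = 0
    for t in spec.terms:
        Xt, pens = t.build(frame)
        blocks.append(Xt)
        stop = col + Xt.shape[1]
        term_map[t.name] = (col, stop)
        if len(pens) == 1:
            penalties.append((t.name, np.arange(col, stop), pens[0]))
        elif t.kind == "smooth" and t.stratum is not None:
            kb = Xt.shape[1] // len(pens)
            for i, S in enumerate(pens):
                idx = np.arange(col + i * kb, col + (i + 1) * kb)
                penalties.append((f"{t.name}[{t.levels[i]}]", idx, S))
        else:  # tensor: two margins on the same columns
            for i, S in enumerate(pens):
                penalties.append((f"{t.name}.m{i + 1}", np.arange(col, stop), S))
        col = stop
    X = np.hstack(blocks)

    para_cols = [i for t in spec.terms if t.kind in ("intercept", "linear")
                 for i in range(*term_map[t.name])]
    if para_cols:
        Xp = X[:, para_cols]
        if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
            names = [t.name for t in spec.terms if t.kind in ("intercept", "linear")]
            raise ValueError(f"parametric block is rank deficient among {names}")
    return Design(X=X, penalties=penalties, term_map=term_map,
                  terms=spec.terms, spec=spec)


def _deviance(d, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(d > 0, d * np.log(d / mu), 0.0)
    return 2.0 * float(np.sum(term - (d - mu)))


def _pirls(X, d, offset, S, beta0=None, tol=1e-8, maxit=200):
    """Penalized IRLS for the Poisson log link with offsets.

    Returns (beta, H, mu, deviance, loglik_kernel); raises on
    non-convergence with the deviance trace attached.
    """
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
        # constant-hazard start: events per unit exposure
        rate = max(d.sum(), 0.5) / np.exp(offset).sum()
        eta = offset + np.log(rate)
    else:
        beta = beta0.copy()
        eta = offset + X @ beta
    mu = np.exp(np.clip(eta, -700, 690))
    dev = _deviance(d, mu)
    trace = [dev]
    for _ in range(maxit):
        W = mu
        z = (eta - offset) + (d - mu) / mu
        XtW = X.T * W
        H = XtW @ X
        try:
            beta_new = linalg.solve(H + S, XtW @ z, assume_a="pos")
        except linalg.LinAlgError:
            beta_new = np.linalg.lstsq(H + S, XtW @ z, rcond=None)[0]
        step = 1.0
        for _half in range(30):
            b_try = beta + step * (beta_new - beta)
            eta_try = offset + X @ b_try
            mu_try = np.exp(np.clip(eta_try, -700, 690))
            dev_try = _deviance(d, mu_try)
            pen_try = dev_try + b_try @ S @ b_try
            if np.isfinite(dev_try) and pen_try <= dev + beta @ S @ beta + 1e-10:
                break
            step *= 0.5
        beta, eta, mu = b_try, eta_try, mu_try
        trace.append(dev_try)
        if abs(dev - dev_try) < tol * (abs(dev_try) + 0.1):
            dev = dev_try
            W = mu
            H = (X.T * W) @ X
            ll = float(np.sum(d * np.clip(eta, -700, 690)) - mu.sum())
            return beta, H, mu, dev, ll
        dev = dev_try
    raise RuntimeError(f"PIRLS did not converge in {maxit} iterations; "
                       f"deviance trace tail: {trace[-5:]}")


def _logdet_pos(M):
    ev = linalg.eigvalsh(M)
    top = max(ev.max(), 1.0)
    pos = ev[ev > _EIG_TOL * top]
    return float(np.sum(np.log(pos))), len(pos)


@dataclass
class FitResult:
    """Fitted PGAM: coefficients, covariance and prediction machinery.

    ``cov`` is the Bayesian posterior covariance ``(X'WX + S)^{-1}``
    evaluated at convergence; ``edf`` the effective degrees of freedom
    ``tr[(X'WX + S)^{-1} X'WX]``.
    """

    beta: np.ndarray
    cov: np.ndarray
    lambdas: dict
    edf: float
    edf_term: dict
    deviance: float
    loglik: float
    method: str
    n_nodes: int
    design: Design
    criterion: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def term_map(self):
        return self.design.term_map

    def coef(self, term: str) -> np.ndarray:
        a, b = self.design.term_map[term]
        return self.beta[a:b]

    def design_rows(self, frame) -> np.ndarray:
        return self.design.rows(frame)

    def predict_log_hazard(self, frame) -> np.ndarray:
        return self.design_rows(frame) @ self.beta

    # -- serialization -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "format": "pgamsurv-fit",
            "version": 1,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "lambdas": self.lambdas,
            "edf": self.edf,
            "edf_term": self.edf_term,
            "deviance": self.deviance,
            "loglik": self.loglik,
            "method": self.method,
            "n_nodes": self.n_nodes,
            "criterion": self.criterion,
            "meta": self.meta,
            "terms": [t.state() for t in self.design.terms],
            "term_map": {k: list(v) for k, v in self.design.term_map.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def load_fit(path) -> FitResult:
    """Load a fit serialized with :meth:`FitResult.to_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "pgamsurv-fit":
        raise ValueError(f"{path} is not a pgamsurv fit container")
    terms = [_term_from_state(s) for s in payload["terms"]]
    design = Design(X=None, penalties=None,
                    term_map={k: tuple(v) for k, v in payload["term_map"].items()},
                    terms=terms, spec=ModelSpec(terms=terms))
    return FitResult(
        beta=np.asarray(payload["beta"]), cov=np.asarray(payload["cov"]),
        lambdas=payload["lambdas"], edf=payload["edf"],
        edf_term=payload["edf_term"], deviance=payload["deviance"],
        loglik=payload["loglik"], method=payload["method"],
        n_nodes=payload["n_nodes"], design=design,
        criterion=payload["criterion"], meta=payload["meta"])


def fit(design: Design, d, offset, method: str = "REML",
        n_nodes: int | None = None, maxit: int = 200) -> FitResult:
    """Fit the penalized Poisson GAM.

    Smoothing parameters are optimized on the log scale by Nelder-Mead on
    the REML (default) or GCV criterion, with PIRLS solving the inner
    coefficient problem; ties between optima are nudged toward the
    smoother fit.  Deterministic given data and settings.
    """
    d = np.asarray(d, dtype=float)
    offset = np.asarray(offset, dtype=float)
    if d.sum() == 0:
        raise ValueError("no events in the data: the hazard level is unidentified")
    if not np.all(np.isfinite(offset)):
        raise ValueError("offsets must be finite")
    if method not in ("REML", "GCV"):
        raise ValueError(f"unknown smoothing criterion {method!r}")
    X = design.X
    n, p = X.shape
    pens = design.penalties

    def total_S(lam):
        S = np.zeros((p, p))
        for lmb, (_, idx, Sb) in zip(lam, pens):
            S[np.ix_(idx, idx)] += lmb * Sb
        return S

    def logdet_S_pos(lam):
        # group penalties sharing the same column block (tensor margins)
        groups: dict[tuple, list[int]] = {}
        for i, (_, idx, _) in enumerate(pens):
            groups.setdefault((idx[0], idx[-1]), []).append(i)
        out = 0.0
        for members in groups.values():
            idx = pens[members[0]][1]
            M = np.zeros((len(idx), len(idx)))
            for i in members:
                M += lam[i] * pens[i][2]
            out += _logdet_pos(M)[0]
        return out

    warm = {"beta": None}

    def criterion(loglam):
        lam = np.exp(np.clip(loglam, -15.0, 15.0))
        S = total_S(lam)
        try:
            beta, H, mu, dev, ll = _pirls(X, d, offset, S, beta0=warm["beta"],
                                          maxit=maxit)
        except RuntimeError:
            return 1e12
        warm["beta"] = beta
        if method == "REML":
            A = H + S
            try:
                c = linalg.cholesky(A, lower=True)
                logdetA = 2.0 * float(np.sum(np.log(np.diag(c))))
            except linalg.LinAlgError:
                logdetA = _logdet_pos(A)[0]
            val = (-ll + 0.5 * beta @ S @ beta + 0.5 * logdetA
                   - 0.5 * logdet_S_pos(lam))
        else:
            edf = float(np.trace(linalg.solve(H + S, H, assume_a="pos")))
            val = n * dev / (n - edf) ** 2
        # deterministic nudge toward the smoother model on flat stretches
        return val - 1e-9 * float(np.sum(np.log(lam)))

    if pens:
        x0 = np.zeros(len(pens))
        res = minimize(criterion, x0, method="Nelder-Mead",
                       options={"xatol": 0.05, "fatol": 1e-6,
                                "maxfev": 200 * max(1, len(pens))})
        loglam = np.clip(res.x, -15.0, 15.0)
        crit = float(res.fun)
    else:
        loglam = np.array([])
        crit = np.nan
    lam = np.exp(loglam)
    S = total_S(lam)
    beta, H, mu, dev, ll = _pirls(X, d, offset, S, beta0=warm["beta"],
                                  maxit=maxit)
    A = H + S
    try:
        cov = linalg.inv(A)
    except linalg.LinAlgError:  # pragma: no cover
        cov = np.linalg.pinv(A)
    cov = 0.5 * (cov + cov.T)
    edf_mat = cov @ H
    edf_col = np.diag(edf_mat)
    edf_term = {name: float(edf_col[a:b].sum())
                for name, (a, b) in design.term_map.items()}
    return FitResult(
        beta=beta, cov=cov,
        lambdas={label: float(l) for (label, _, _), l in zip(pens, lam)},
        edf=float(edf_col.sum()), edf_term=edf_term, deviance=dev, loglik=ll,
        method=method, n_nodes=n_nodes or 0, design=design, criterion=crit)


def fit_model(expanded: ExpandedData, formula: str, method: str = "REML") -> FitResult:
    """Convenience wrapper: parse, build and fit in one call."""
    spec = ModelSpec.from_formula(formula)
    design = build_design(expanded, spec)
    return fit(design, expanded.d, expanded.offset, method=method,
               n_nodes=expanded.n_nodes)


def test_term_zero(fit_result: FitResult, term: str):
    """Wald test of a term's coefficient block against zero.

    Applied to a ``by``-smooth this is the proportionality-of-hazards
    test; to a parametric treatment coefficient, the constant-effect test.
    Returns ``(statistic, df, p_value)``; a singular covariance subblock
    falls back to its pseudo-inverse with rank-adjusted df and a warning.
    """
    if term not in fit_result.design.term_map:
        raise KeyError(f"term {term!r} not in fit; have "
                       f"{sorted(fit_result.design.term_map)}")
    a, b = fit_result.design.term_map[term]
    theta = fit_result.beta[a:b]
    V = fit_result.cov[a:b, a:b]
    if np.allclose(theta, 0.0):
        return 0.0, len(theta), 1.0
    ev = linalg.eigvalsh(V)
    rank = int(np.sum(ev > _EIG_TOL * max(ev.max(), 1.0)))
    if rank < len(theta):
        warnings.warn(f"covariance subblock of {term!r} is rank deficient "
                      f"({rank}/{len(theta)}); using pseudo-inverse",
                      stacklevel=2)
        stat = float(theta @ np.linalg.pinv(V, rcond=1e-10) @ theta)
    else:
        stat = float(theta @ linalg.solve(V, theta, assume_a="pos"))
    return stat, rank, float(stats.chi2.sf(stat, rank))
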
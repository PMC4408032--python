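"""Penalized spline bases for log-hazard smooths.

Implements the cubic regression spline in its cardinal (function-value)
parameterization: coefficients are the values of a natural cubic spline at
the knots, the wiggliness penalty is the integrated squared second
derivative, and the penalty null space is exactly the constant and linear
functions.  Evaluation outside the knot range extrapolates linearly, which
keeps predicted log-hazards tame beyond the observed follow-up.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CubicRegressionSpline", "quantile_knots", "sum_to_zero_constraint"]


def quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    """``k`` strictly increasing knots at quantiles of ``x``.

    Falls back to fewer knots when ``x`` has too few distinct values.
    """
    if k < 3:
        raise ValueError("need at least 3 knots")
    qs = np.quantile(np.asarray(x, dtype=float), np.linspace(0, 1, k))
    knots = np.unique(qs)
    if len(knots) < 3:
        raise ValueError("fewer than 3 distinct knot locations in the data")
    return knots


class CubicRegressionSpline:
    """Natural cubic regression spline on a fixed knot sequence.

    The ``j``-th coefficient is the spline's value at knot ``j``; second
    derivatives at the knots follow from the natural end conditions via
    ``delta = F beta``, and the penalty is ``S = D' B^{-1} D`` (both in the
    standard banded construction from the knot spacings).
    """

    def __init__(self, knots: np.ndarray):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 3:
            raise ValueError("need a 1-d array of at least 3 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        k = len(knots)
        h = np.diff(knots)
        D = np.zeros((k - 2, k))
        B = np.zeros((k - 2, k - 2))
        for i in range(k - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        self._h = h
        # second-derivative map, padded with the natural end conditions
        F = np.linalg.solve(B, D)
        self._F = np.vstack([np.zeros(k), F, np.zeros(k)])
        self.penalty = D.T @ np.linalg.solve(B, D)
        self.penalty = 0.5 * (self.penalty + self.penalty.T)

    @property
    def n_basis(self) -> int:
        return len(self.knots)

    def design(self, x) -> np.ndarray:
        """Model-matrix rows evaluating the spline at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        kn, h, F = self.knots, self._h, self._F
        k = len(kn)
        X = np.zeros((len(x), k))

        inside = (x >= kn[0]) & (x <= kn[-1])
        if np.any(inside):
            xi = x[inside]
            j = np.clip(np.searchsorted(kn, xi, side="right") - 1, 0, k - 2)
            hj = h[j]
            am = (kn[j + 1] - xi) / hj
            ap = (xi - kn[j]) / hj
            cm = ((kn[j + 1] - xi) ** 3 / hj - hj * (kn[j + 1] - xi)) / 6.0
            cp = ((xi - kn[j]) ** 3 / hj - hj * (xi - kn[j])) / 6.0
            rows = cm[:, None] * F[j] + cp[:, None] * F[j + 1]
            idx = np.arange(len(xi))
            rows[idx, j] += am
            rows[idx, j + 1] += ap
            X[inside] = rows

        for left in (True, False):
            mask = x < kn[0] if left else x > kn[-1]
            if not np.any(mask):
                continue
            b = kn[0] if left else kn[-1]
            base = self.design(np.array([b]))[0]
            dbase = self._deriv_at_boundary(left)
            X[mask] = base + (x[mask] - b)[:, None] * dbase
        return X

    def _deriv_at_boundary(self, left: bool) -> np.ndarray:
        kn, h, F = self.knots, self._h, self._F
        k = len(kn)
        row = np.zeros(k)
        if left:
            row[0] -= 1.0 / h[0]
            row[1] += 1.0 / h[0]
            row = row - h[0] / 6.0 * (2.0 * F[0] + F[1])
        else:
            row[k - 2] -= 1.0 / h[-1]
            row[k - 1] += 1.0 / h[-1]
            row = row + h[-1] / 6.0 * (2.0 * F[k - 1] + F[k - 2])
        return row


def sum_to_zero_constraint(X: np.ndarray) -> np.ndarray:
    """Null-space basis ``Z`` absorbing the constraint ``1' X beta = 0``.

    Reparameterizing columns as ``X Z`` removes the data-mean direction so a
    smooth can coexist with an explicit intercept.
    """
    c = X.sum(axis=0)[:, None]
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]
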
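"""Expansion of censored survival records into Poisson pseudo-observations.

Each subject's likelihood contribution ``h(F)^delta exp(-∫_E^F h)`` is
approximated by replacing the cumulative-hazard integral with a
Gauss-Lobatto sum.  Because both endpoints are quadrature nodes, the exit
time (and hence the event) is represented exactly: the record becomes
``n`` Poisson rows with response 1 only at the exit node of an event, and
offset ``log w`` carrying the quadrature weight as exposure.  Maximizing
the resulting Poisson likelihood approximates maximum likelihood on the
exact censored-data likelihood, with error controlled by the quadrature
order (see :mod:`pgamsurv.quadrature`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quadrature import _canonical_lobatto

__all__ = ["SurvivalRecord", "ExpandedData", "expand", "approximate_loglik"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: observed on ``(entry, exit]`` with event indicator.

    ``event`` is 1 if the subject failed at ``exit`` and 0 if censored
    there; ``entry > 0`` encodes delayed entry (left truncation).
    """

    id: object
    entry: float
    exit: float
    event: int
    covariates: dict = field(default_factory=dict)
    stratum: object = None
    cluster: object = None

    def __post_init__(self):
        if self.event not in (0, 1):
            raise ValueError(f"record {self.id}: event must be 0 or 1, got {self.event}")
        if not self.exit > self.entry:
            raise ValueError(
                f"record {self.id}: exit ({self.exit}) must exceed entry ({self.entry}); "
                "no subject can fail at its entry time")
        if self.entry < 0:
            raise ValueError(f"record {self.id}: negative entry time {self.entry}")


@dataclass
class ExpandedData:
    """Poisson pseudo-observations at Gauss-Lobatto nodes.

    ``frame`` has one row per (record, node): columns ``id``, ``t`` (node
    time), ``offset`` (log quadrature weight), ``d`` (0/1 response), plus
    carried covariates and optional ``stratum``/``cluster`` labels.
    """

    frame: pd.DataFrame
    n_nodes: int
    covariate_names: list[str]

    @property
    def t(self) -> np.ndarray:
        return self.frame["t"].to_numpy()

    @property
    def d(self) -> np.ndarray:
        return self.frame["d"].to_numpy()

    @property
    def offset(self) -> np.ndarray:
        return self.frame["offset"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.offset)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def expand(records: list[SurvivalRecord], n_nodes: int = 10) -> ExpandedData:
    """Expand survival records into ``n_nodes`` pseudo-observations each.

    The per-record Lobatto rule lives on ``[entry, exit]``; weights sum to
    the follow-up length and the event (if any) sits on the exit node.
    ``n_nodes = 2`` collapses the rule to the trapezoid on the endpoints
    and is allowed only with a warning.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if n_nodes == 2:
        warnings.warn("n_nodes=2 is the bare trapezoid rule; use >= 3 "
                      "for a usable hazard resolution", stacklevel=2)
    if not records:
        raise ValueError("no records to expand")

    bad = [r.id for r in records if not r.exit > r.entry]
    if bad:  # records constructed without validation (e.g. __new__ hacks)
        raise ValueError(f"records with exit <= entry: {bad}")

    x, w = _canonical_lobatto(int(n_nodes))
    n = len(records)
    entry = np.array([r.entry for r in records])
    exit_ = np.array([r.exit for r in records])
    half = 0.5 * (exit_ - entry)
    if np.any(half * np.min(w) <= 0):
        raise ValueError("degenerate interval produced a zero quadrature weight")

    t = entry[:, None] + half[:, None] * (x[None, :] + 1.0)
    t[:, 0] = entry
    t[:, -1] = exit_
    wts = half[:, None] * w[None, :]
    d = np.zeros((n, n_nodes), dtype=int)
    d[:, -1] = [r.event for r in records]

    cov_names: list[str] = []
    for r in records:
        for k in r.covariates:
            if k not in cov_names:
                cov_names.append(k)

    cols = {
        "id": np.repeat([r.id for r in records], n_nodes),
        "t": t.ravel(),
        "offset": np.log(wts).ravel(),
        "d": d.ravel(),
    }
    for k in cov_names:
        cols[k] = np.repeat([r.covariates.get(k) for r in records], n_nodes)
    if any(r.stratum is not None for r in records):
        cols["stratum"] = np.repeat([r.stratum for r in records], n_nodes)
    if any(r.cluster is not None for r in records):
        cols["cluster"] = np.repeat([r.cluster for r in records], n_nodes)

    return ExpandedData(frame=pd.DataFrame(cols), n_nodes=int(n_nodes),
                        covariate_names=cov_names)


def approximate_loglik(expanded: ExpandedData, hazard) -> float:
    """Quadrature-approximate log-likelihood ``sum d log h - w h``.

    ``hazard`` is called as ``hazard(t, row_frame)`` if it accepts two
    arguments, else as ``hazard(t)``; it must be strictly positive at all
    node times.
    """
    t = expanded.t
    try:
        h = np.asarray(hazard(t, expanded.frame), dtype=float)
    except TypeError:
        h = np.asarray(hazard(t), dtype=float)
    h = np.broadcast_to(h, t.shape)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise ValueError("hazard must be finite and strictly positive at all nodes")
    d = expanded.d
    w = expanded.weights
    return float(np.sum(d * np.log(h)) - np.sum(w * h))
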
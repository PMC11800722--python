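"""Semiparametric latency machinery for the AFT mixture cure model.

The latency part models the log failure time of uncured subjects as
``log T = beta' X + eps`` with an unspecified error survival function
``S_eps``.  Three pieces live here:

* residuals ``eps_ij(beta) = log t_ij - beta' X_ij``;
* a weighted nonparametric estimator of ``S_eps`` -- an exponentiated
  negative weighted cumulative hazard with jumps at the distinct
  uncensored residuals, forced to 0 beyond the largest one (the zero-tail
  restriction that keeps the cure fraction identifiable);
* Buckley--James-type imputation of censored log responses by the
  conditional expectation of the error beyond the censoring residual,
  taken under the discrete distribution implied by the step estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClusteredDataset

__all__ = [
    "StepSurvival",
    "ResidualSet",
    "compute_residuals",
    "estimate_error_survival",
    "impute_log_response",
]


@dataclass
class StepSurvival:
    """Right-continuous non-increasing step survival function.

    ``knots`` are the strictly increasing jump locations; ``values[s]`` is
    the survival value just after ``knots[s]``.  Before the first knot the
    function equals 1 (estimator convention: no mass below the smallest
    uncensored residual); strictly beyond the last knot it equals 0.
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knots.ndim != 1 or self.values.shape != self.knots.shape:
            raise ValueError("knots and values must be 1-D arrays of equal length")
        if self.knots.size == 0:
            raise ValueError("a step survival function needs at least one knot")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(np.diff(self.values) > 1e-12) or self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("values must be non-increasing and within [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def __call__(self, y) -> np.ndarray:
        """Evaluate S(y): jumps happen *at* each knot, so S(knot) still
        includes that knot's mass; S is 0 strictly beyond the last knot."""
        y = np.asarray(y, dtype=float)
        # number of knots strictly below y
        k = np.searchsorted(self.knots, y, side="left")
        vals = np.where(k == 0, 1.0, self.values[np.maximum(k - 1, 0)])
        out = np.where(y > self.knots[-1], 0.0, vals)
        return out if out.ndim else float(out)

    def masses(self) -> np.ndarray:
        """Probability mass at each knot implied by the step function.

        The mass at the last knot absorbs the whole remaining tail, matching
        the zero-tail restriction.
        """
        before = np.concatenate(([1.0], self.values[:-1]))
        m = before - self.values
        m[-1] = before[-1]  # S == 0 beyond the last knot
        return m

    def to_table(self) -> np.ndarray:
        """Two-column (knot, survival-just-after-knot) array for export."""
        return np.column_stack([self.knots, self.values])


@dataclass
class ResidualSet:
    """AFT residuals with event indicators and uncured-probability weights."""

    eps: np.ndarray
    delta: np.ndarray
    g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        self.delta = np.asarray(self.delta, dtype=int)
        if self.g is not None:
            self.g = np.asarray(self.g, dtype=float)
            if np.any((self.g < 0) | (self.g > 1)):
                raise ValueError("weights g must lie in [0, 1]")
            if np.any(self.g[self.delta == 1] != 1.0):
                raise ValueError("g must equal 1 for subjects with an observed event")


def compute_residuals(beta: np.ndarray, dataset: ClusteredDataset) -> ResidualSet:
    """eps_ij(beta) = log t_ij - beta' X_ij, input order preserved."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (dataset.p_x,):
        raise ValueError(f"beta has shape {beta.shape}, expected ({dataset.p_x},)")
    eps = np.log(dataset.time) - dataset.X @ beta
    return ResidualSet(eps=eps, delta=dataset.event)


def estimate_error_survival(res: ResidualSet) -> StepSurvival:
    """Weighted nonparametric estimator of the error survival function.

    S(y) = exp(-sum_{s: tau_s < y} d_s / W_s) where tau_1 < ... < tau_k are
    the distinct uncensored residuals, d_s the number of events tied at
    tau_s, and W_s = sum of weights g over the risk set {eps >= tau_s}.
    S is set to 0 strictly beyond tau_k.
    """
    if res.g is None:
        raise ValueError("residual set has no weights g")
    delta = res.delta
    if not np.any(delta == 1):
        raise ValueError("cannot estimate the error distribution with no observed events")
    eps, g = res.eps, res.g
    knots, d = np.unique(eps[delta == 1], return_counts=True)
    # weight in risk set at each knot: sum of g over eps >= tau_s
    order = np.argsort(eps, kind="stable")
    eps_sorted = eps[order]
    g_sorted = g[order]
    suffix = np.concatenate([np.cumsum(g_sorted[::-1])[::-1], [0.0]])
    first_at_least = np.searchsorted(eps_sorted, knots, side="left")
    W = suffix[first_at_least]
    if np.any(W <= 0):
        s = int(np.where(W <= 0)[0][0])
        raise ValueError(f"degenerate risk set: zero total weight at knot {knots[s]!r}")
    values = np.exp(-np.cumsum(d / W))
    return StepSurvival(knots=knots, values=values)


def impute_log_response(
    beta: np.ndarray,
    S: StepSurvival,
    res: ResidualSet,
    dataset: ClusteredDataset,
) -> np.ndarray:
    """Buckley--James-type imputed log responses.

    Uncensored subjects keep ``log t``.  A censored subject gets
    ``beta' X + E[eps | eps > eps_ij]`` under the discrete error
    distribution implied by ``S`` (support restricted to knots strictly
    above the subject's residual).  A censored residual at or beyond the
    last knot is imputed with the last knot itself.
    """
    beta = np.asarray(beta, dtype=float)
    logt = np.log(dataset.time)
    eps, delta = res.eps, res.delta
    m = S.masses()
    tm = S.knots * m
    # suffix sums over knots strictly greater than eps
    suffix_m = np.concatenate([np.cumsum(m[::-1])[::-1], [0.0]])
    suffix_tm = np.concatenate([np.cumsum(tm[::-1])[::-1], [0.0]])
    k = np.searchsorted(S.knots, eps, side="right")  # first knot > eps
    den = suffix_m[k]
    num = suffix_tm[k]
    with np.errstate(invalid="ignore", divide="ignore"):
        cond_exp = np.where(den > 0, num / np.where(den > 0, den, 1.0), S.knots[-1])
    xb = dataset.X @ beta
    return np.where(delta == 1, logt, xb + cond_exp)
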
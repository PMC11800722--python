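"""EM + GEE estimation of the marginal semiparametric AFT mixture cure model.

The observed-data model mixes a cured fraction with a latency distribution:

    S(t | X, Z) = 1 - pi(Z) + pi(Z) * S_eps(log t - beta' X)

with a logistic incidence part pi(Z) = expit(gamma' [1, Z]) and a
semiparametric AFT latency part.  Estimation alternates an E-step --
posterior uncured-probability weights ``g`` for the censored subjects --
with an M-step that solves two generalized estimating equations sharing
those weights: a weighted-logistic GEE for gamma (responses g) and a
Buckley--James-type linear GEE for beta (responses: imputed log times).
Both GEEs carry a working correlation matrix whose parameter rho and
dispersion phi are re-estimated from standardized residuals inside an
inner loop.  The outer loop stops when the sum of squared changes in
(gamma, beta) drops below ``FitControl.em_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .correlation import (
    CorrelationEstimate,
    build_working_matrix,
    estimate_dispersion,
    estimate_rho,
)
from .data import ClusteredDataset, FitControl
from .latency import (
    ResidualSet,
    StepSurvival,
    compute_residuals,
    estimate_error_survival,
    impute_log_response,
)

__all__ = [
    "IncidenceModel",
    "LatencyModel",
    "FitResult",
    "posterior_uncured_weight",
    "solve_incidence_gee",
    "solve_latency_gee",
    "fit",
]

_PI_CLIP = 1e-10


class ConvergenceError(RuntimeError):
    """A GEE solver failed to converge (e.g. separation in the incidence part)."""


@dataclass
class IncidenceModel:
    """Logistic model for the uncured probability; gamma[0] is the intercept."""

    gamma: np.ndarray

    def uncured_probability(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return expit(self.gamma[0] + Z @ self.gamma[1:])


@dataclass
class LatencyModel:
    """AFT model for the uncured (no intercept) plus the error survival curve."""

    beta: np.ndarray
    error_survival: StepSurvival


@dataclass
class FitResult:
    incidence: IncidenceModel
    latency: LatencyModel
    corr_incidence: CorrelationEstimate
    corr_latency: CorrelationEstimate
    weights: np.ndarray
    n_em_iter: int
    converged: bool
    trace: list = field(default_factory=list)

    @property
    def gamma(self) -> np.ndarray:
        return self.incidence.gamma

    @property
    def beta(self) -> np.ndarray:
        return self.latency.beta

    def to_dict(self) -> dict:
        return {
            "gamma": self.incidence.gamma.tolist(),
            "beta": self.latency.beta.tolist(),
            "rho1": self.corr_incidence.rho,
            "phi1": self.corr_incidence.phi,
            "rho2": self.corr_latency.rho,
            "phi2": self.corr_latency.phi,
            "n_em_iter": self.n_em_iter,
            "converged": self.converged,
        }


def posterior_uncured_weight(pi, S_at_eps, delta):
    """Posterior probability of being uncured given the observed data.

    g = delta + (1 - delta) * pi * S / (1 - pi + pi * S).  Events force
    g = 1; a censored subject whose residual lies beyond the last knot has
    S = 0 and is classified cured (g = 0).
    """
    pi = np.asarray(pi, dtype=float)
    S = np.asarray(S_at_eps, dtype=float)
    delta = np.asarray(delta)
    num = pi * S
    g = np.where(delta == 1, 1.0, num / (1.0 - pi + num))
    return g if g.ndim else float(g)


def _q_inverses(structure: str, rho: float, sizes) -> dict[int, np.ndarray]:
    return {n: np.linalg.inv(build_working_matrix(structure, rho, n)) for n in sizes}


def solve_incidence_gee(
    g: np.ndarray,
    Z: np.ndarray,
    groups: dict[int, np.ndarray],
    structure: str = "independent",
    rho: float = 0.0,
    phi: float = 1.0,
    gamma_start: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Solve the weighted-logistic GEE for gamma by damped Fisher scoring.

    The estimating function is  sum_i D_i' V_i^{-1} (g_i - pi_i)  with
    D_i = A_i Z_i*, V_i = A_i^{1/2} Q_i A_i^{1/2} phi, A_i the diagonal of
    pi(1-pi) and Z_i* the design including the intercept column.  ``groups``
    maps cluster size -> (n_clusters, size) array of subject row indices.
    Under the independent structure with responses in {0,1} the root is the
    ordinary logistic MLE.
    """
    g = np.asarray(g, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    N = len(g)
    Zfull = np.column_stack([np.ones(N), Z])
    p = Zfull.shape[1]
    Qinv = _q_inverses(structure, rho, groups.keys())
    gamma = np.zeros(p) if gamma_start is None else np.asarray(gamma_start, dtype=float).copy()

    def score_and_info(gam, want_info=True):
        pi = expit(Zfull @ gam)
        pi = np.clip(pi, _PI_CLIP, 1 - _PI_CLIP)
        a = np.sqrt(pi * (1 - pi))
        r = g - pi
        U = np.zeros(p)
        J = np.zeros((p, p)) if want_info else None
        for n, idx in groups.items():
            Zg = Zfull[idx]                       # (C, n, p)
            ag = a[idx]
            t = (r[idx] / ag) @ Qinv[n].T         # (C, n)
            U += np.einsum("cnp,cn->p", Zg, ag * t)
            if want_info:
                Za = Zg * ag[..., None]
                J += np.einsum("cnp,nm,cmq->pq", Za, Qinv[n], Za)
        return U / phi, (J / phi if want_info else None)

    U, J = score_and_info(gamma)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(J, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular working information matrix: {exc}") from exc
        # step halving on the score norm
        norm0 = float(np.dot(U, U))
        lam = 1.0
        for _h in range(50):
            cand = gamma + lam * step
            U_new, _ = score_and_info(cand, want_info=False)
            if float(np.dot(U_new, U_new)) <= norm0 or norm0 < 1e-24:
                break
            lam *= 0.5
        else:
            raise ConvergenceError("incidence GEE: step halving exhausted (possible separation)")
        delta_step = lam * step
        gamma = gamma + delta_step
        if np.linalg.norm(gamma) > 1e3:
            raise ConvergenceError("incidence GEE diverging (possible separation)")
        if float(np.max(np.abs(delta_step))) < tol:
            return gamma
        U, J = score_and_info(gamma)
    raise ConvergenceError(f"incidence GEE did not converge in {max_iter} iterations")


def solve_latency_gee(
    g: np.ndarray,
    yhat: np.ndarray,
    X: np.ndarray,
    groups: dict[int, np.ndarray],
    structure: str = "independent",
    rho: float = 0.0,
    phi: float = 1.0,
    B_scale: float = 1.0,
) -> np.ndarray:
    """Solve the Buckley--James-type linear GEE for beta with yhat frozen.

    beta = [sum_i (X_i - 1 xbar')' W_i G_i X_i]^{-1}
           sum_i (X_i - 1 xbar')' W_i G_i yhat_i,
    W_i = (B_i^{1/2} Q_i B_i^{1/2} phi)^{-1} with B_i = B_scale * I; xbar is
    the unweighted grand mean of X.  The common scalar B_scale * phi cancels
    in the root, so it affects only the scale of the estimating function.
    """
    if B_scale <= 0:
        raise ValueError("B_scale must be positive")
    g = np.asarray(g, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    Xc = X - X.mean(axis=0)
    scale = 1.0 / (B_scale * phi)
    Qinv = _q_inverses(structure, rho, groups.keys())
    A = np.zeros((p, p))
    b = np.zeros(p)
    for n, idx in groups.items():
        Xg = X[idx]                    # (C, n, p)
        Xcg = Xc[idx]
        Gg = g[idx]                    # (C, n)
        QG = Qinv[n][None, :, :] * Gg[:, None, :]   # (C, n, n): Qinv @ diag(g)
        left = np.einsum("cnp,cnm->cmp", Xcg, QG)   # (Xc' Qinv G)' pieces
        A += np.einsum("cmp,cmq->pq", left, Xg) * scale
        b += np.einsum("cmp,cm->p", left, yhat[idx]) * scale
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            f"singular latency system (g-weighted centered design rank-deficient): {exc}"
        ) from exc


def _grouped(values: np.ndarray, groups: dict[int, np.ndarray]) -> list[np.ndarray]:
    """Per-cluster residual vectors (within-cluster input order preserved)."""
    out: list[np.ndarray] = []
    for _n, idx in groups.items():
        out.extend(values[idx])
    return out


def fit(
    dataset: ClusteredDataset,
    structure_incidence: str = "independent",
    structure_latency: str = "independent",
    control: FitControl | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Fit the marginal semiparametric AFT mixture cure model.

    Parameters
    ----------
    dataset
        Clustered right-censored survival data (needs at least one event).
    structure_incidence, structure_latency
        Working correlation structure for the cure statuses and for the
        log times of the uncured: ``independent``, ``exchangeable`` or
        ``ar1``.  Under ``independent`` the dispersion is fixed at 1, so
        the GEEs reduce exactly to the no-correlation estimating equations.
    control
        Convergence control; defaults to :class:`FitControl`.
    init
        Optional (gamma, beta) starting values; by default gamma starts at
        the ordinary logistic regression of the event indicator on Z and
        beta at the OLS of log t on centered X among the uncensored.
    """
    control = control or FitControl()
    delta = dataset.event
    if not np.any(delta == 1):
        raise ValueError("cannot fit a cure model with no observed events")
    groups = dataset.size_groups()
    Z, X = dataset.Z, dataset.X
    logt = np.log(dataset.time)

    # (a) initialization
    if init is not None:
        gamma = np.asarray(init[0], dtype=float).copy()
        beta = np.asarray(init[1], dtype=float).copy()
    else:
        gamma = solve_incidence_gee(delta.astype(float), Z, groups, tol=control.inner_tol)
        ev = delta == 1
        Xe = X[ev] - X[ev].mean(axis=0)
        ye = logt[ev] - logt[ev].mean()
        beta = np.linalg.lstsq(Xe, ye, rcond=None)[0]
    res = compute_residuals(beta, dataset)
    g = delta.astype(float)
    S = estimate_error_survival(ResidualSet(res.eps, delta, g))

    corr1 = CorrelationEstimate(0.0, 1.0, structure_incidence)
    corr2 = CorrelationEstimate(0.0, 1.0, structure_latency)
    pZ1 = dataset.p_z + 1
    pX = dataset.p_x
    trace: list[dict] = []
    converged = False
    n_iter = 0

    for m in range(1, control.max_em_iter + 1):
        n_iter = m
        theta_old = np.concatenate([gamma, beta])

        # (b) E-step: posterior uncured weights at the current parameters
        pi = np.clip(expit(np.column_stack([np.ones(len(logt)), Z]) @ gamma), _PI_CLIP, 1 - _PI_CLIP)
        g = posterior_uncured_weight(pi, S(res.eps), delta)

        # (c)(i) error-survival update with the new weights
        S = estimate_error_survival(ResidualSet(res.eps, delta, g))

        # (c)(ii)-(iv) inner loop: correlation/dispersion moments + GEE solves
        for _inner in range(control.max_inner_iter):
            inner_old = np.concatenate([gamma, beta])
            yhat = impute_log_response(beta, S, res, dataset)
            if structure_incidence == "independent":
                corr1 = CorrelationEstimate(0.0, 1.0, "independent")
            else:
                pi = np.clip(
                    expit(np.column_stack([np.ones(len(logt)), Z]) @ gamma),
                    _PI_CLIP, 1 - _PI_CLIP,
                )
                r1 = (g - pi) / np.sqrt(pi * (1 - pi))
                phi1 = estimate_dispersion(r1, pZ1)
                corr1 = estimate_rho(_grouped(r1, groups), structure_incidence, phi1, pZ1)
            if structure_latency == "independent":
                corr2 = CorrelationEstimate(0.0, 1.0, "independent")
            else:
                # The latency model carries no intercept (the error location
                # absorbs it), so the raw residuals yhat - X beta have a
                # nonzero mean; center them before forming Pearson-type
                # moments, mirroring the centering of X in the GEE itself.
                r2 = yhat - X @ beta
                r2 = r2 - r2.mean()
                phi2 = estimate_dispersion(r2, pX)
                corr2 = estimate_rho(_grouped(r2, groups), structure_latency, phi2, pX)
            gamma = solve_incidence_gee(
                g, Z, groups, structure_incidence, corr1.rho, corr1.phi,
                gamma_start=gamma, tol=control.inner_tol,
            )
            resid_var = float(np.var(yhat - X @ beta))
            beta = solve_latency_gee(
                g, yhat, X, groups, structure_latency, corr2.rho, corr2.phi,
                B_scale=max(resid_var, 1e-12),
            )
            res = compute_residuals(beta, dataset)
            if float(np.sum((np.concatenate([gamma, beta]) - inner_old) ** 2)) < control.inner_tol:
                break

        diff = float(np.sum((np.concatenate([gamma, beta]) - theta_old) ** 2))
        trace.append({"iter": m, "gamma": gamma.copy(), "beta": beta.copy(), "diff": diff})
        # (d) stopping rule on the sum of squared parameter changes
        if diff < control.em_tol:
            converged = True
            break

    if not converged:
        import warnings

        warnings.warn(
            f"EM did not converge in {control.max_em_iter} iterations "
            f"(last sum of squared changes {trace[-1]['diff']:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )

    pi = np.clip(expit(np.column_stack([np.ones(len(logt)), Z]) @ gamma), _PI_CLIP, 1 - _PI_CLIP)
    g = posterior_uncured_weight(pi, S(res.eps), delta)
    return FitResult(
        incidence=IncidenceModel(gamma=gamma),
        latency=LatencyModel(beta=beta, error_survival=S),
        corr_incidence=corr1,
        corr_latency=corr2,
        weights=np.asarray(g),
        n_em_iter=n_iter,
        converged=converged,
        trace=trace,
    )
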
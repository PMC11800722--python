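"""Working correlation structures and moment estimation of (rho, phi).

The GEEs for the incidence and latency parts each carry a working
correlation matrix: independent (identity), exchangeable (all off-diagonal
entries equal rho) or first-order autoregressive (entry (j, j') equal to
rho^|j-j'|).  The correlation parameter rho and the dispersion phi are
estimated by moment formulas on standardized residuals: phi is the mean
squared residual with a degrees-of-freedom correction, and rho averages
residual cross-products over within-cluster pairs (all pairs for
exchangeable, adjacent pairs for AR(1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WorkingStructure",
    "CorrelationEstimate",
    "build_working_matrix",
    "estimate_dispersion",
    "estimate_rho",
    "rho_validity_interval",
]

_STRUCTURES = ("independent", "exchangeable", "ar1")
_CLAMP_MARGIN = 1e-6


def _check_structure(structure: str) -> str:
    if structure not in _STRUCTURES:
        raise ValueError(f"unknown working structure {structure!r}; expected one of {_STRUCTURES}")
    return structure


# WorkingStructure is a closed string enumeration; plain strings keep the API light.
WorkingStructure = str


@dataclass
class CorrelationEstimate:
    """Moment estimates of the working correlation parameter and dispersion."""

    rho: float
    phi: float
    structure: str = "independent"
    clamped: bool = False


def rho_validity_interval(structure: str, n_max: int) -> tuple[float, float]:
    """Open interval of rho values yielding positive-definite working
    matrices for every cluster size up to ``n_max``."""
    _check_structure(structure)
    if structure == "independent":
        return (0.0, 0.0)
    if structure == "ar1":
        return (-1.0, 1.0)
    lo = -1.0 / (n_max - 1) if n_max > 1 else -1.0
    return (lo, 1.0)


def build_working_matrix(structure: str, rho: float, n: int) -> np.ndarray:
    """n-by-n working correlation matrix for the given structure."""
    _check_structure(structure)
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    if structure == "independent":
        return np.eye(n)
    lo, hi = rho_validity_interval(structure, n)
    if not (lo < rho < hi) and not (n == 1 and -1 < rho < 1):
        raise ValueError(
            f"rho={rho} outside the positive-definite interval ({lo}, {hi}) "
            f"for {structure} with n={n}"
        )
    if structure == "exchangeable":
        Q = np.full((n, n), rho)
        np.fill_diagonal(Q, 1.0)
        return Q
    j = np.arange(n)
    return rho ** np.abs(j[:, None] - j[None, :])


def estimate_dispersion(residuals: Sequence[np.ndarray] | np.ndarray, p: int) -> float:
    """Dispersion phi = sum of squared standardized residuals / (N - p).

    ``p`` counts the regression parameters of the part the residuals come
    from (incidence: pZ + 1 including the intercept; latency: pX).
    """
    flat = np.concatenate([np.ravel(r) for r in residuals]) if isinstance(residuals, (list, tuple)) \
        else np.ravel(np.asarray(residuals, dtype=float))
    N = flat.size
    if N - p <= 0:
        raise ValueError(f"non-positive degrees of freedom: N={N}, p={p}")
    return float(np.sum(flat**2) / (N - p))


def estimate_rho(
    residuals: Sequence[np.ndarray],
    structure: str,
    phi: float,
    p: int,
) -> CorrelationEstimate:
    """Moment estimate of the working correlation parameter rho.

    ``residuals`` is one 1-D array per cluster, in within-cluster order
    (order matters for AR(1)).  Exchangeable averages the cross-products of
    all distinct within-cluster pairs; AR(1) averages lag-1 products.  The
    denominator carries the same degrees-of-freedom correction ``p`` as the
    dispersion.  Estimates falling outside the positive-definiteness
    interval are clamped to the boundary minus a small margin, with a
    warning.
    """
    _check_structure(structure)
    if structure == "independent":
        raise ValueError("rho is not estimated under the independent structure")
    if phi <= 0:
        raise ValueError("phi must be positive")
    sizes = np.array([len(np.ravel(r)) for r in residuals])
    n_max = int(sizes.max()) if sizes.size else 0
    if n_max <= 1:
        raise ValueError("rho is not estimable: every cluster has size 1")
    # stack clusters of equal size so the cross-products vectorize
    stacks: dict[int, list[np.ndarray]] = {}
    for r in residuals:
        r = np.ravel(np.asarray(r, dtype=float))
        stacks.setdefault(len(r), []).append(r)
    cross = 0.0
    if structure == "exchangeable":
        denom = float(np.sum(sizes * (sizes - 1) / 2.0) - p)
        for sz, rs in stacks.items():
            R = np.vstack(rs)
            cross += float(np.sum((R.sum(axis=1) ** 2 - np.sum(R * R, axis=1)) / 2.0))
    else:  # ar1
        denom = float(np.sum(np.maximum(sizes - 1, 0)) - p)
        for sz, rs in stacks.items():
            if sz > 1:
                R = np.vstack(rs)
                cross += float(np.sum(R[:, :-1] * R[:, 1:]))
    if denom <= 0:
        raise ValueError(f"non-positive degrees of freedom in rho estimate (denominator {denom})")
    rho = cross / (phi * denom)
    lo, hi = rho_validity_interval(structure, n_max)
    clamped = False
    if rho <= lo or rho >= hi:
        new = float(np.clip(rho, lo + _CLAMP_MARGIN, hi - _CLAMP_MARGIN))
        warnings.warn(
            f"moment estimate rho={rho:.4f} outside PD interval ({lo:.4f}, {hi:.4f}); "
            f"clamped to {new:.6f}",
            RuntimeWarning,
            stacklevel=2,
        )
        rho, clamped = new, True
    return CorrelationEstimate(rho=float(rho), phi=float(phi), structure=structure, clamped=clamped)
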
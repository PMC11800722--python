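"""Cluster-resampling bootstrap for the AFT mixture cure fit.

Within-cluster dependence rules out resampling individual subjects, so
each bootstrap replicate draws K whole clusters with replacement and
refits the model.  Standard errors are the across-replicate standard
deviations (over converged replicates); confidence intervals use the
normal approximation ``estimate +/- z * se`` by default, with percentile
intervals as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import ClusteredDataset, FitControl
from .fit import FitResult, fit

__all__ = ["BootstrapSummary", "bootstrap_fit"]


@dataclass
class BootstrapSummary:
    """Bootstrap replicates and per-parameter summaries.

    ``estimates`` stacks (gamma, beta, rho1, rho2) per converged replicate;
    ``n_failed`` counts replicates dropped for non-convergence (reported,
    never silently discarded).
    """

    B: int
    parameter_names: list[str]
    estimates: np.ndarray        # (n_converged, pZ+1+pX+2)
    point: np.ndarray            # estimates from the original fit
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_failed: int
    ci_method: str = "normal"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.parameter_names,
                "estimate": self.point,
                "se": self.se,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
            }
        )


def _stack_params(result: FitResult) -> np.ndarray:
    return np.concatenate(
        [result.gamma, result.beta, [result.corr_incidence.rho, result.corr_latency.rho]]
    )


def bootstrap_fit(
    dataset: ClusteredDataset,
    structures: tuple[str, str],
    control: FitControl | None = None,
    B: int = 100,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
    ci_method: str = "normal",
    base_result: FitResult | None = None,
) -> BootstrapSummary:
    """Cluster bootstrap of the full fit.

    Each replicate samples K clusters with replacement (clusters are never
    split; duplicates get fresh labels so they count as independent
    clusters), refits with the same working structures, and records
    (gamma, beta, rho1, rho2).  Replicate r depends only on (seed, r).
    ``base_result`` (the fit on the original data) is computed if not
    supplied; its estimates warm-start each replicate's EM.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    control = control or FitControl()
    if base_result is None:
        base_result = fit(dataset, structures[0], structures[1], control)
    point = _stack_params(base_result)
    K = dataset.n_clusters
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)

    rows, n_failed = [], 0
    init = (base_result.gamma, base_result.beta)
    for r in range(B):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (r,))
        )
        picks = rng.integers(0, K, K)
        sample = dataset.subset_clusters(picks)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = fit(sample, structures[0], structures[1], control, init=init)
            if res.converged:
                rows.append(_stack_params(res))
            else:
                n_failed += 1
        except (np.linalg.LinAlgError, ValueError, RuntimeError):
            n_failed += 1

    if not rows:
        raise RuntimeError("all bootstrap replicates failed to converge")
    if n_failed > 0.2 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed; standard errors may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    est = np.vstack(rows)
    se = est.std(axis=0, ddof=1)
    if ci_method == "normal":
        z = norm.ppf(0.5 + level / 2.0)
        lo, hi = point - z * se, point + z * se
    elif ci_method == "percentile":
        alpha = (1.0 - level) / 2.0
        lo = np.quantile(est, alpha, axis=0)
        hi = np.quantile(est, 1.0 - alpha, axis=0)
    else:
        raise ValueError("ci_method must be 'normal' or 'percentile'")
    names = (
        [f"gamma{j}" for j in range(len(base_result.gamma))]
        + [f"beta{j + 1}" for j in range(len(base_result.beta))]
        + ["rho1", "rho2"]
    )
    return BootstrapSummary(
        B=B,
        parameter_names=names,
        estimates=est,
        point=point,
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        n_failed=n_failed,
        ci_method=ci_method,
    )
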
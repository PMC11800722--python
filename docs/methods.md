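# Methods

This note records the model, the estimation procedure, the numerical
conventions, and the design choices made where more than one reasonable
option existed.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

Clustered right-censored data: subject *j* of cluster *i* (i = 1..K,
j = 1..n_i, N = Σ n_i) has failure time T̃_ij, censoring time C_ij
(conditionally independent of T̃ given covariates), observed time
T_ij = min(T̃, C) and indicator δ_ij.  A latent cure status ω_ij ∈ {0, 1}
marks whether the subject is susceptible; cured subjects never fail
(T̃ = ∞), so δ = 1 implies ω = 1 while censored subjects have unknown ω.

* Incidence: P(ω = 1 | Z) = π(Z) = expit(γ'[1, Z]); γ has pZ + 1 entries,
  intercept first.
* Latency: log T̃ | (ω = 1) = β'X + ε with unspecified error survival S_ε.
  β has pX entries and **no intercept** — with S_ε unrestricted, an
  intercept is not identified and is absorbed into the error location.

Within a cluster, cure statuses are correlated with each other and so are
the log times of uncured subjects; across clusters everything is
independent.  The model is *marginal*: γ and β describe population-average
effects, and within-cluster correlation enters only through working
correlation matrices that buy efficiency, never consistency.

## Estimation: EM with GEE M-steps

With ω known, the complete-data likelihood separates into a Bernoulli part
(γ) and an AFT part (β, S_ε).  The EM algorithm replaces ω for censored
subjects by its posterior expectation at the current parameters,

    g = δ + (1 − δ) · πS_ε(ε) / (1 − π + πS_ε(ε)),     ε = log t − β'X.

Because S_ε is forced to 0 beyond its last knot (below), a censored
subject whose residual exceeds every uncensored residual gets g = 0 and is
classified cured.

**Error survival.**  S_ε is estimated by the weighted exponentiated
negative cumulative hazard

    Ŝ_ε(y) = exp( − Σ_{s: τ_s < y} d_s / Σ_{(i,j): ε_ij ≥ τ_s} g_ij ),

with knots τ_1 < … < τ_k at the distinct uncensored residuals, d_s the
number of events tied at τ_s, and weighted risk sets (censored subjects
tied with a knot stay in its risk set; a subject with g = 0 contributes
nothing).  The **zero-tail restriction** sets Ŝ_ε(y) = 0 strictly beyond
τ_k; without it, mass escaping to +∞ is confounded with the cure fraction.
With unit weights this is exactly exp(−Nelson–Aalen), which the tests use
as an independent oracle.

**Imputed responses.**  The β-equation is linear in a Buckley–James-type
response: ŷ = log t for events, and for censored subjects
ŷ = β'X + E[ε | ε > ε_ij] under the discrete distribution implied by Ŝ_ε
(mass at each knot; the last knot absorbs the tail so masses sum to 1).
Conventions: the conditional expectation runs over knots **strictly
above** the subject's residual (open lower limit of the defining
integral); a censored residual at or beyond τ_k is imputed with τ_k itself
— the standard Buckley–James tail convention, consistent with the
zero-tail rule.  Imputations are never below the observed log t
(conditioning on survival past it), which is asserted in the tests.

**The two GEEs.**  Holding g and ŷ fixed, the M-step solves

* incidence: Σ_i D_i' (A_i^{1/2} Q_i^{(1)} A_i^{1/2} φ₁)^{-1} (g_i − π_i) = 0,
  with D_i = A_i [1, Z_i], A_i = diag(π(1−π)) — a weighted-logistic GEE
  solved by damped Fisher scoring with step-halving (max 50 halvings, then
  a non-convergence error; a diverging ‖γ‖ flags separation).  With the
  identity working matrix and binary responses this is ordinary logistic
  ML, which the tests check against an independent implementation.
* latency: Σ_i (X_i − 1 x̄')' (B_i^{1/2} Q_i^{(2)} B_i^{1/2} φ₂)^{-1} G_i
  (ŷ_i − X_i β) = 0, linear in β and solved densely.  x̄ is the
  **unweighted** grand mean of X (centering stands in for the absorbed
  intercept).  B_i is a common scalar — the sample variance of ŷ − β'X,
  recomputed each inner pass; any common scalar cancels in the root, so
  this choice affects only the scale of the estimating function (asserted
  by a scale-invariance test).

**Working correlation moments.**  Q^(1), Q^(2) are independent (identity),
exchangeable (off-diagonals ρ) or AR(1) (ρ^|j−j'|).  ρ and the dispersion
φ are estimated by moments of standardized residuals: incidence residuals
r^(1) = (g − π)/√(π(1−π)) with degrees-of-freedom constant pZ + 1;
latency residuals r^(2) = ŷ − β'X **centered at their grand mean** with
constant pX.  The centering is this package's convention: the latency
model has no intercept, so raw residuals have a nonzero mean, and
uncentered cross-products would credit that common offset — inflated
further by the imputed responses of cured-classified subjects — to ρ₂.
Centering makes the moments proper Pearson-type quantities and mirrors the
centering of X in the GEE itself.  φ = Σr²/(N − p); exchangeable ρ̂ sums
all within-cluster pairs over φ(Σ n_i(n_i−1)/2 − p); AR(1) sums lag-1
pairs over φ(Σ(n_i−1) − p).  Estimates outside the positive-definiteness
interval (exchangeable: (−1/(n_max−1), 1); AR(1): (−1, 1)) are clamped to
the boundary ∓ 1e−6 with a warning, keeping every working matrix
invertible.  Under the **independent** structure φ is fixed at 1 and ρ is
never estimated, so both GEEs reduce exactly to the no-correlation
estimating equations — this makes the independent fit a faithful internal
baseline.

**Iteration.**  (a) initialize γ by ordinary logistic regression of δ on
Z, β by OLS of log t on centered X among events, Ŝ_ε from the residuals
with g = δ; (b) E-step; (c) update Ŝ_ε, then iterate {moments → γ-solve →
β-solve → recompute residuals/ŷ} to an inner tolerance of 1e−6 (sum of
squared parameter changes, cap 20 passes); (d) stop when the sum of
squared changes of the concatenated (γ, β) between consecutive EM
iterations falls below 1e−4 (ρ, φ and Ŝ_ε are excluded from the metric).
Exceeding 100 EM iterations returns `converged=False` with a warning
rather than raising.  `fit` accepts optional (γ, β) starting values;
bootstrap and simulation refits warm-start from the original estimates,
which shortens the EM without changing its fixed point.

## Cluster bootstrap

Each replicate draws K whole clusters with replacement (duplicates get
fresh labels, so the working-correlation bookkeeping treats them as the
conditionally independent clusters they are), refits, and records
(γ̂, β̂, ρ̂₁, ρ̂₂).  Standard errors are across-replicate standard
deviations over **converged** replicates; failures are counted and
reported, with a warning above 20%.  Intervals default to the normal
approximation (estimate ± 1.96·se), matching how coverage is evaluated in
the simulation harness; percentile intervals are available.  Replicate r
depends only on (seed, r), so runs are bit-reproducible and parallelizable.
Default B = 100.

## Synthetic data generator

The generator emulates a marginal mixture-cure process with clustered
dependence (defaults in parentheses):

* K clusters (100) of common size n (3; a size vector is accepted);
* two covariates per subject, Bernoulli(0.5) and Uniform(−1, 1), shared by
  the incidence and latency parts;
* incidence truth γ = (0.3, 0.6, 0.9) — implied population cure fraction
  0.365 by quadrature; γ₀ = −0.3 gives exactly 0.5;
* latency truth β = (0.6, 0.9) with **unit-variance** Gaussian errors —
  the error scale is not separately specified by the study design, and
  unit variance is the natural normalization when the association
  parameter is described as a correlation;
* within-cluster association ζ for cure statuses and τ for errors (0.4 and
  0.8), patterned exchangeably or AR(1);
* independent Uniform(0, c) censoring (c = 50).  At these defaults the
  censoring fraction is ≈0.40 (cure 0.365) and ≈0.53 (cure 0.5), as the
  acceptance script recomputes.

Correlated cure statuses use the Emrich–Piedmonte construction: for each
within-cluster pair, the latent normal correlation ρ̃ solves
Φ₂(z_{π₁}, z_{π₂}; ρ̃) = π₁π₂ + ζ_target·√(π₁(1−π₁)π₂(1−π₂)); latent
normals with those correlations are thresholded at the normal quantiles of
π.  Φ₂ is evaluated by 64-node Gauss–Legendre quadrature of the
correlation-integral representation (validated against an independent CDF
implementation to ~1e−9), and the root is found by bracket-safeguarded
Newton using the bivariate normal density as the exact derivative,
de-duplicated across pairs on (π₁, π₂, target) rounded to 1e−6.

Two Bernoulli marginals cannot attain every correlation.  When a pair's
target exceeds its Fréchet bound (which happens regularly at ζ = 0.4 with
covariate-dependent probabilities), the generator caps the target at
0.999× the bound; consequently the *achieved* average association sits
slightly below ζ, and the replication-average ρ̂₁ under the exchangeable
working structure lands near 0.36 rather than 0.40 — a property of the
design, not an estimator bias.  If the pairwise solutions still assemble
into a non-positive-definite matrix, the nearest correlation matrix
(eigenvalue clipping at 1e−8, diagonal rescaled) is substituted; the
generator errors if that repair would move any entry by more than 0.05.
The scalar `ep_pairwise_latent_correlation` raises on infeasible targets
instead of capping, reporting the attainable range.

What the generator does **not** emulate: covariate-dependent or
informative censoring, informative cluster size, non-Gaussian error
copulas, heavy-tailed or heteroscedastic errors, and covariates that
differ between the incidence and latency parts.  Passing tests therefore
certify the estimator under a clean, correctly specified marginal
process — not robustness to those violations.

## Monte Carlo harness and scale

`run_simulation_study` feeds identical datasets to every working-structure
pair (common random numbers), aggregates bias, empirical variance Var,
average bootstrap variance Var*, and the coverage of 95% bootstrap
intervals, each with a Monte Carlo standard error (bias: sd/√R; variance:
normal-theory fourth-moment formula; coverage: binomial).  Relative
efficiency is the ratio of MSE = bias² + Var, computed over the
replicates where both fits converged (pairwise exclusion); non-converged
replicates are counted and reported, never silently dropped.  Replicate r
derives its generator from (seed, r).

Default problem sizes: the reproduction suite and the acceptance script
use R = 300 replications for the efficiency/variance/correlation targets
and R = 200 with B = 50 for coverage — a deliberate scale-down from the
original 1000/100 design that keeps every check inside a few minutes while
the stated three-MC-standard-error tolerances account for the extra noise.

## Known limitations

* The sandwich (asymptotic) covariance of (γ̂, β̂) is not implemented;
  inference is bootstrap-only, which is also what the simulation harness
  evaluates.
* ρ̂₂ summarizes the correlation of *imputed* responses.  Pairs involving
  censored subjects carry no information about the error correlation (the
  imputation is a function of the censoring time alone), so ρ̂₂ is an
  attenuated measure of the latent error correlation τ — useful as a
  working parameter and as a descriptive index, not as an estimate of τ.
* Clusters of size 1 are handled, but ρ is inestimable if *all* clusters
  are singletons (an explicit error).
* Left truncation, interval censoring, time-varying covariates and missing
  data are out of scope.
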
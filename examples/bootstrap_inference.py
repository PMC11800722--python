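"""Cluster-bootstrap standard errors and confidence intervals.

Within-cluster dependence invalidates subject-level resampling, so whole
clusters are drawn with replacement and the model refitted per replicate.
"""

from curegee import SimConfig, bootstrap_fit, simulate_dataset

dataset = simulate_dataset(SimConfig(), seed=7)
summary = bootstrap_fit(
    dataset, ("exchangeable", "exchangeable"), B=100, seed=7
)

print(summary.to_frame().round(3).to_string(index=False))
print(f"\n{summary.n_failed} of {summary.B} replicates failed to converge")
# Each row: the point estimate from the original fit, the bootstrap
# standard error (sd across replicate refits), and the 95% normal-
# approximation interval.  Intervals for beta that exclude 0 indicate a
# covariate effect on the failure time of uncured subjects.
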
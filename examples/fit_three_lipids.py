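"""Fit the causal effects of three lipid fractions on disease risk.

Simulates a summary dataset at the scale of a large lipid-GWAS /
CAD-consortium analysis (185 variants, exposure associations from ~189k
participants, outcome associations from ~22k cases and ~65k controls) with
true causal log odds ratios (0.4, -0.1, 0.3) per SD of LDL-c, HDL-c and
triglycerides, then fits the joint model by MCMC and prints the estimates
the way consortium analyses report them: odds ratios per 1 SD increase with
95% credible intervals.
"""

import numpy as np

from mvmr import CorrelationSpec, fit_mcmc, generate_dataset

ds, truth = generate_dataset(
    J=185, K=3, beta=[0.4, -0.1, 0.3],
    ld_block_sizes=[3, 3, 2, 2, 2],  # a few variants in modest LD (< 0.25)
    seed=7,
)
fit = fit_mcmc(ds, CorrelationSpec.lipid_default(), chains=4,
               iterations=2000, warmup=500, seed=7)

print("Causal odds ratios of disease per 1 SD increase in each lipid fraction")
print(f"({ds.n_active} variants; posterior mean, 95% credible interval,")
print(" two-sided posterior p-value):\n")
for v, name in enumerate(fit.risk_factor_names):
    print(
        f"  {name:>4}: OR {fit.odds_ratio[v]:.2f} "
        f"({fit.or_ci_lower[v]:.2f} to {fit.or_ci_upper[v]:.2f}), "
        f"p = {fit.p_labels()[v]}   [true OR {np.exp(truth.beta[v]):.2f}]"
    )
print(f"\nSampler diagnostics: max split R-hat {fit.rhat.max():.3f}, "
      f"min effective sample size {fit.ess.min():.0f}")
print("An OR above 1 means the risk factor raises disease risk; the "
      "intervals should cover the true ORs used to simulate the data.")
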
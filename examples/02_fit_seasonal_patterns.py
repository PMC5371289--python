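"""Fit the hierarchical Dirichlet model and inspect the posterior.

Simulates one species, pretreats the raw table into yearly proportion
patterns, runs the MCMC fit at the fast profile, and prints the posterior
mean period patterns with convergence diagnostics.
"""

import numpy as np

from phenomatch import (FAST_MCMC, SimulationConfig, average_monthly,
                        fit_model, generate_dataset,
                        make_trajectory_scenario, significant_pattern_change,
                        to_ecological_year, to_yearly_patterns)

config = SimulationConfig(
    species=[make_trajectory_scenario("/", "T", 2.0, species_id="sp")],
    seed=7)
table, truth = generate_dataset(config)

monthly = to_ecological_year(average_monthly(table), 3)
patterns = to_yearly_patterns(monthly)
sample = fit_model(patterns, config.periods, mcmc=FAST_MCMC)

sp = sample["sp"]
for pid in sp.period_ids:
    print(pid, np.round(sp.pattern_mean(pid), 3))
print("Each row is the posterior mean yearly pattern of one regime; the "
      "period-1 peak sits two months later than in periods 2 and 3, as "
      "generated.")

print(f"\nmax R-hat: {max(sp.rhat.values()):.3f} "
      "(< 1.05 means the three chains agree)")
print(f"posterior median concentration: {np.median(sp.pooled_lam()):.0f} "
      "(how tightly single years track the period mean)")

sig, months = significant_pattern_change(sample, "sp", "P1", "P2")
print(f"\nP1 vs P2 significant: {sig}, months with disjoint 95% CIs: "
      f"{months}")
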
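"""Phenological indicators and predator-prey overlap on posterior draws.

Fits a predator and a prey whose temporal overlap collapses in the last
regime, then prints the five indicators and the overlap index with 95%
credibility intervals.
"""

from phenomatch import (FAST_MCMC, SimulationConfig, average_monthly,
                        fit_model, generate_dataset,
                        indicator_posterior, make_interaction_scenario,
                        to_ecological_year, to_yearly_patterns)

pred, prey = make_interaction_scenario("\\", shift_months=3.0)
config = SimulationConfig(species=[pred, prey],
                          interactions=[(pred.species_id, prey.species_id)],
                          seed=11)
table, _ = generate_dataset(config)
patterns = to_yearly_patterns(to_ecological_year(average_monthly(table), 3))
sample = fit_model(patterns, config.periods, mcmc=FAST_MCMC)

ind = indicator_posterior(sample,
                          interactions=[(pred.species_id, prey.species_id)])

print("Species indicators (posterior mean [95% CI]):")
sub = ind.species_summary.query("species == 'pair_prey'")
for _, r in sub.iterrows():
    print(f"  {r['period']} {r['indicator']:>4}: {r['mean']:6.2f} "
          f"[{r['ci_low']:5.2f}, {r['ci_high']:5.2f}]")
print("T/Q10/Q50/Q90 are month coordinates (e.g. 5.5 = mid May-June "
      "boundary for a January year-start); Tr is a number of months.")

print("\nPredator-prey temporal overlap per regime:")
for _, r in ind.overlap_summary.iterrows():
    print(f"  {r['period']}: {100 * r['mean']:.0f}% "
          f"[{100 * r['ci_low']:.0f}%, {100 * r['ci_high']:.0f}%]")
print("The drop in the final regime is the generated mismatch: the prey "
      "pattern was translated three months away from the predator's.")
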
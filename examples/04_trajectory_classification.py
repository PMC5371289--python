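"""End-to-end trajectory classification of a known phenological change.

Generates a species whose seasonal peak dips two months earlier in the
middle regime (a "C" trajectory), runs the full pipeline, and prints the
symbol table the classification stage produces.
"""

from phenomatch import (FAST_MCMC, SimulationConfig, average_monthly,
                        classify_species_indicators, fit_model,
                        generate_dataset, indicator_posterior,
                        make_trajectory_scenario, summarize,
                        to_ecological_year, to_yearly_patterns)

periods = (("P1", 1, 8), ("P2", 9, 16), ("P3", 17, 24))
config = SimulationConfig(
    periods=periods,
    species=[make_trajectory_scenario("C", "T", 2.0, species_id="dipper")],
    seed=3)
table, _ = generate_dataset(config)
patterns = to_yearly_patterns(to_ecological_year(average_monthly(table), 3))
sample = fit_model(patterns, periods, mcmc=FAST_MCMC)
ind = indicator_posterior(sample)
calls = classify_species_indicators(ind, [p[0] for p in periods])

tables = summarize(calls, presence={"dipper": (True, True, True)})
print(tables.species_table.to_string())
print("\nEach cell shows the trajectory glyph with the count of "
      "significant pairwise period differences in brackets; 'C (2)' for "
      "the peak-timing indicator T recovers the generated "
      "earlier-then-back trajectory.")
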
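import numpy as np
import pytest

from phenomatch import (McmcSettings, SimulationConfig, average_monthly,
                        fit_model, generate_dataset, make_trajectory_scenario,
                        to_ecological_year, to_yearly_patterns)

#: reduced settings for unit tests; statistical acceptance tests use the
#: package's fast profile instead
TINY_MCMC = McmcSettings(n_chains=3, n_burnin=300, n_keep_per_chain=500)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def patterns_from_config(config):
    table, truth = generate_dataset(config)
    monthly = to_ecological_year(average_monthly(table), 3)
    return to_yearly_patterns(monthly), truth


@pytest.fixture(scope="session")
def shifted_fit():
    """A fitted 3-period species whose period-2 peak is 3 months early."""
    periods = (("P1", 1, 8), ("P2", 9, 16), ("P3", 17, 24))
    sc = make_trajectory_scenario("C", "T", 3.0, species_id="shifted")
    config = SimulationConfig(periods=periods, species=[sc], seed=7)
    table, truth = generate_dataset(config)
    monthly = to_ecological_year(average_monthly(table), 3)
    patterns = to_yearly_patterns(monthly)
    sample = fit_model(patterns, periods, mcmc=TINY_MCMC)
    return sample, sc
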
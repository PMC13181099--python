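import pytest

from lupinest import synthetic_data as synth


@pytest.fixture(scope="session")
def sim_config():
    return synth.SimulationConfig(rng_seed=7)


@pytest.fixture(scope="session")
def germination_trials(sim_config):
    return synth.simulate_germination(sim_config)


@pytest.fixture(scope="session")
def ordinal_records(sim_config):
    return synth.simulate_soil_experiment(sim_config)


@pytest.fixture(scope="session")
def growth_records(sim_config):
    return synth.simulate_ph_experiment(sim_config)
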
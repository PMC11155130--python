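import pytest

from wsdecipher.synthetic_data import SimulationConfig, generate_all

MASTER_SEED = 7


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, sim_config):
    """One full synthetic input bundle shared by the integration tests."""
    out = tmp_path_factory.mktemp("bundle")
    ground_truth = generate_all(sim_config, out)
    return out, ground_truth
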
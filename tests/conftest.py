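import pytest

from hgtscreen.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """The default study conditions: 100 native, 20 transferred and 30
    contaminant genes with well-separated bit-score margins."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def default_report(default_config, default_dataset):
    from hgtscreen.pipeline import run_all

    return run_all(default_config, dataset=default_dataset)
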
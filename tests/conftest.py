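import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracle` importable

from crelink.pipeline import PipelineConfig, run_pipeline
from crelink.synth import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_all(sim_config)


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    return run_pipeline(dataset, PipelineConfig())
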
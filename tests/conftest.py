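import numpy as np
import pytest

from drygpp import pipeline
from drygpp.synthetic_data import ScenarioConfig


@pytest.fixture(scope="session")
def config():
    """Default scenario with a fixed seed."""
    return ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def result(config):
    """One full pipeline run, shared across tests that only read it."""
    return pipeline.run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
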
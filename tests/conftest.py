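import numpy as np
import pytest
from hypothesis import settings

from cbgtloop import SimulationConfig, default_circuit, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def circuit():
    return default_circuit()


@pytest.fixture(scope="session")
def short_run(circuit):
    """32 s of the default circuit at a pinned seed, shared across tests."""
    return simulate(circuit, SimulationConfig(duration=32.0, seed=0))


@pytest.fixture(scope="session")
def long_run(circuit):
    """128 s of the default circuit (the study's standard run length)."""
    return simulate(circuit, SimulationConfig(duration=128.0, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
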
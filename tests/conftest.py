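import numpy as np
import pytest

from teacelm.datasets import GeneratorConfig, generate_dataset
from teacelm.pso import PSOConfig
from teacelm.training import TrainerConfig


@pytest.fixture(scope="session")
def default_dataset():
    """The 172-row calibrated synthetic dataset used throughout."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def large_dataset():
    """A 50,000-row draw for Monte-Carlo checks of the generator algebra."""
    return generate_dataset(GeneratorConfig(n_samples=50_000, seed=1))


@pytest.fixture
def fast_trainer():
    """A reduced swarm budget that still optimizes, for cheap tests."""
    return TrainerConfig(
        seed=7, pso=PSOConfig(n_particles=10, max_iterations=30))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
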
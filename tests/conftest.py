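import numpy as np
import pytest

from shipstrike.grid_io import RunConfig
from shipstrike.synthetic_data import ScenarioSpec, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A compact but fully featured synthetic scenario (10x10 grid)."""
    return generate_scenario(ScenarioSpec(grid_shape=(10, 10), seed=42))


@pytest.fixture()
def quick_config():
    return RunConfig(n_iterations=50, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
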
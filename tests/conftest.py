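import numpy as np
import pytest

import volvar
from volvar.config import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Full five-step / six-ROI vocabulary at a size that keeps tests fast."""
    return SimulationConfig(n_participants=30, n_scans=3, n_runs=5, seed=7)


@pytest.fixture(scope="session")
def small_ratios(small_config):
    table = volvar.generate_volume_table(small_config)
    return volvar.ratio_correct(table)


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    return SimulationConfig.noise_free(n_participants=8, n_scans=3, n_runs=2, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
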
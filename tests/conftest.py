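import numpy as np
import pytest

from ssvepbench.synthetic_data import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def high_snr_dataset():
    """Small, nearly noise-free session: 4 runs x 4 frequencies at +40 dB."""
    return generate_dataset(SimulationConfig(n_runs=4, snr_db=40.0, seed=1))


@pytest.fixture(scope="session")
def moderate_dataset():
    """Default-condition session at reduced run count for fast unit tests."""
    return generate_dataset(SimulationConfig(n_runs=4, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
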
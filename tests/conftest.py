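import numpy as np
import pytest

from cbci.pipeline import analyse_dataset
from cbci.simulate import SimConfig, simulate_dataset

#: Desk-scale default benchmark: 10 participants, accuracies 0.65-0.95,
#: 336 decision trials, seed 42.  EEG is simulated at a reduced rate and
#: montage (128 Hz, 16 channels) to keep the suite within its time budget;
#: both are configurable up to 2048 Hz / 64 channels.
BENCHMARK_CONFIG = SimConfig(fs_raw=128, n_channels=16, seed=42)


@pytest.fixture(scope="session")
def benchmark_dataset():
    return simulate_dataset(BENCHMARK_CONFIG)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_dataset):
    """Full pipeline output (all four schemas) on the default benchmark."""
    return analyse_dataset(benchmark_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
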
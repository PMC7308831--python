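import numpy as np
import pytest

import ecgca


@pytest.fixture(scope="session")
def phi_half():
    """CR 0.5 sensing matrix at the standard window size."""
    return ecgca.make_sensing_matrix(125, 250, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects, 30 train / 10 test each, default misalignment and noise."""
    return ecgca.generate_dataset(4, 30, 10, rng_seed=21)


@pytest.fixture(scope="session")
def aligned_noiseless_dataset():
    """4 subjects with no misalignment and no noise (every beat identical up
    to per-beat jitter turned off): the easy regime for every framework."""
    return ecgca.generate_dataset(
        4, 30, 10, shift_range=(0, 0), noise_sd=0.0, rng_seed=22, beat_jitter=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
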
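import numpy as np
import pytest

import dissogp as dg


@pytest.fixture(scope="session")
def noiseless_ds():
    """Noise-free study-design dataset from the default ground truth."""
    return dg.simulate_profiles(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_ds():
    """Study-design dataset with 1% Gaussian measurement noise."""
    return dg.simulate_profiles(noise_sd=1.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
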
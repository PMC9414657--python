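import numpy as np
import pytest

import ppgpeakkit as pk


@pytest.fixture(scope="session")
def clean_bank():
    """Small bank of simulated clean PPG records (shared across tests)."""
    return pk.build_clean_bank(n_records=6, record_duration_s=40.0, seed=11)


@pytest.fixture(scope="session")
def noise_bank():
    return pk.build_noise_bank(n_records=6, record_duration_s=40.0, seed=12)


@pytest.fixture(scope="session")
def default_model():
    """Untrained default network (random weights, zero biases)."""
    return pk.build_model(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
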
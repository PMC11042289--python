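import numpy as np
import pytest

from resikit import protocol as pr


@pytest.fixture(scope="session")
def three_state_traj():
    """Unbiased feature trajectory on the three-state potential (shared: slow)."""
    return pr.three_state_training_data(seed=1, n_steps=2_000_000, stride=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
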
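import numpy as np
import pytest

from tremorkit import TremorSimParams, simulate_recording


@pytest.fixture(scope="session")
def default_recording():
    """One 30 s / 1000 Hz synthetic tremor recording with default physiology."""
    return simulate_recording(TremorSimParams(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
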
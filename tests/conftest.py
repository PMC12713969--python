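import numpy as np
import pytest

from oroflow import make_params, simulate_subject


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_subject():
    """One simulated default-preset subject, small enough for fast tests."""
    params = make_params(
        "default", duration=300.0, fs=50.0, mouth_fraction=0.2, clock_offset=4.0, seed=42
    )
    return simulate_subject(params)
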
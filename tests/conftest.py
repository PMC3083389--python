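import numpy as np
import pytest

from dispersim import validate_config


@pytest.fixture
def tiny_config():
    """Small, fast world used by most unit tests."""
    return validate_config(dict(
        width=12, height=12, n_vessels=4, vessel_regime="static",
        total_input=200.0, n_steps=50, window=10, init_cells=30, seed=42,
    ))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
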
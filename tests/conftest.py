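import numpy as np
import pytest

from grnplast.dynamics import DynamicsParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def fast_params():
    """Integration parameters with a reduced step cap for quick tests."""
    return DynamicsParams(max_steps=100_000)
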
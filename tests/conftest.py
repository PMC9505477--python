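import numpy as np
import pytest

from heanet.autodiff import set_default_dtype


@pytest.fixture
def f64():
    """Run a test with float64 parameters/promotions for tight oracle tolerances."""
    with set_default_dtype(np.float64):
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
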
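import numpy as np
import pytest

from nfvisco import PronyModel


@pytest.fixture(scope="session")
def three_param_model():
    """Fitted three-parameter model at the lower pulling rate (GPa, ps)."""
    return PronyModel(0.103, ((0.827, 87.866),))


@pytest.fixture(scope="session")
def two_param_model():
    """Fitted two-parameter (Maxwell) model at the higher pulling rate."""
    return PronyModel(0.0, ((2.0, 100.0),))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
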
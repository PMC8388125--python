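import numpy as np
import pytest

from slpkinetics import (
    RateParametersModel1,
    RateParametersModel2,
    SignalResponse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def model2_fast():
    """Two-step parameters in the fast stopped-flow regime (Kd ~ 10 nM)."""
    return RateParametersModel2(k1=1.614e8, k_minus1=1.612, k2=10.0)


@pytest.fixture
def model2_weak():
    """Two-step parameters with Kd = 100 uM, kapp ~ 9.09e4."""
    return RateParametersModel2(k1=1e6, k_minus1=100.0, k2=10.0)


@pytest.fixture
def fp_response():
    return SignalResponse(r_free=0.05, r_bound=0.25)
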
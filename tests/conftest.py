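import numpy as np
import pytest

from p3dif import DIFParams, SQUParams, generate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def seq_even():
    """192-trial equiprobable binary sequence."""
    return generate_sequence(2, 192, [0.5, 0.5], seed=7)


@pytest.fixture
def seq_biased():
    """192-trial [0.3, 0.7] binary sequence."""
    return generate_sequence(2, 192, [0.3, 0.7], seed=11)


@pytest.fixture
def dif_params():
    """Published-optimum digital-filter parameters."""
    return DIFParams()


@pytest.fixture
def squ_params():
    return SQUParams(P_k=(0.5, 0.5))
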
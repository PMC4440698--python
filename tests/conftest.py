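import numpy as np
import pytest

from fprsim.greens import PairParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_pair():
    """sigma=1 nm, D_AB=20 nm^2/us, k_a=10 nm^3/us."""
    return PairParams(1.0, 10.0, 10.0, 10.0)


@pytest.fixture
def absorbing_pair():
    return PairParams(1.0, 10.0, 10.0, np.inf)
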
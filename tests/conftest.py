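import numpy as np
import pytest

from seqclock.params import population_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def e_params():
    return population_params("E")


@pytest.fixture
def i_params():
    return population_params("I")
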
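import numpy as np
import pytest

from burstschool import ModelParams


@pytest.fixture
def params():
    """Standard parameter set at the schooling reference point."""
    return ModelParams(gamma_att=0.22, gamma_ali=0.6, k=1, n_fish=100)


@pytest.fixture
def small_params():
    """Cheap small-group parameters for event-loop tests."""
    return ModelParams(gamma_att=0.3, gamma_ali=0.3, k=1, n_fish=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
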
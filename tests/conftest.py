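import numpy as np
import pytest
from hypothesis import settings

from gliofront import Grid1D, ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def grid():
    return Grid1D.regular(b_omega=1.0, n_nodes=500)


@pytest.fixture
def small_grid():
    return Grid1D.regular(b_omega=1.0, n_nodes=64)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
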
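import numpy as np
import pytest

from cawave import default_parameters
from cawave.model_core import GridSpec, ModelParameters
from dataclasses import replace


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def tiny_params(params):
    """4 x 4 um domain with 1-um CRU lattice: fast unit-test configuration."""
    return replace(
        params,
        grid=GridSpec(length_x=4.0, length_y=4.0),
        cru=replace(params.cru, lx=1.0, ly=1.0),
        t_end=20.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
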
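import numpy as np
import pytest

from virowave.core import InitialCondition, ModelParams, Plateau


@pytest.fixture
def params():
    """Reference 1D parameter set (alpha = 580, q_v = 0.167)."""
    return ModelParams()


@pytest.fixture
def params_high():
    """Reference 1D set with the high burst-size pair (alpha = 3500, q_v = 1)."""
    return ModelParams(alpha=3500.0, q_v=1.0)


@pytest.fixture
def params_2d():
    return ModelParams.reference(dimension=2)


@pytest.fixture
def ic(params):
    return InitialCondition.from_params(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def no_infection_ic(params, u_height=None, u_radius=None):
    """Initial condition without virus or infected cells."""
    return InitialCondition(
        u0=Plateau(0.9 * params.K if u_height is None else u_height,
                   params.R_u if u_radius is None else u_radius),
        i0=Plateau(0.0, 0.0),
        v0=Plateau(0.0, 0.0),
    )
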
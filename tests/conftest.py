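import numpy as np
import pytest
from hypothesis import settings

from tmemix.grid import Grid2D
from tmemix import spatial as sp
from tmemix import fixtures as fx

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid32() -> Grid2D:
    return Grid2D.square(32, 150.0)


@pytest.fixture(scope="session")
def params() -> sp.SpatialParams:
    return sp.SpatialParams()


@pytest.fixture()
def mixture_state(grid32):
    """Smooth random four-species state, S well below 1."""
    return fx.make_mixture_fixture(grid32, seed=7, scale=0.15)


@pytest.fixture()
def nest_state(grid32, params):
    return sp.make_initial_condition("single-nest", grid32, params, nest_radius=20.0)
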
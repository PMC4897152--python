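import numpy as np
import pytest

from stenoflow import (
    BodyAcceleration,
    Grid,
    PressureForcing,
    SolverConfig,
    StenosisGeometry,
)


@pytest.fixture
def default_geometry():
    return StenosisGeometry()


@pytest.fixture
def straight_geometry():
    return StenosisGeometry(lambda_=0.0)


@pytest.fixture
def small_grid():
    """Coarse grid for fast unit tests (still above the validity minimum)."""
    return Grid(M=20, N=20, domain_length=10.0, dt=0.005)


@pytest.fixture
def steady_forcing():
    return PressureForcing(p0=0.1, p1=0.0, omega=0.0), BodyAcceleration(a0=0.0, omega=0.0)


@pytest.fixture
def solver_config():
    return SolverConfig()


def assert_boundary_conditions(state):
    """No-slip at the wall, axis symmetry and zero radial axis flow, exactly."""
    assert np.all(state.u[:, -1] == 0.0)
    assert np.all(state.v[:, -1] == 0.0)
    assert np.all(state.v[:, 0] == 0.0)
    assert np.all(state.u[:, 0] == state.u[:, 1])
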
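"""Shared fixtures: kinetic defaults and scaled-down lattice settings."""
import numpy as np
import pytest

from depolysim import KineticParams, MetabolicParams
from depolysim.params import SpatialConfig


@pytest.fixture
def kin():
    """Reference kinetics: equal turnover numbers, k = 0.82, km = 0.5."""
    return KineticParams()


@pytest.fixture
def kin_unit():
    """Unit turnover numbers for hand arithmetic."""
    return KineticParams(k_exo=1.0, k_endo=1.0)


@pytest.fixture
def metab():
    return MetabolicParams()


@pytest.fixture
def small_lattice():
    """A scaled lattice for fast spatial tests (CFL-safe at D_0 = 30)."""
    return SpatialConfig(nx=12, ny=12, dt=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
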
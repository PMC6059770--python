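import numpy as np
import pytest

from clocktradeoff.dynamics import ClockGeometry
from clocktradeoff.signals import make_square_wave


@pytest.fixture(scope="session")
def clean_signal_short():
    """Five clean days at the default resolution."""
    return make_square_wave(period=24.0, day_fraction=0.5, t_end=120.0, dt=0.01)


@pytest.fixture(scope="session")
def clean_signal_coarse():
    """Thirty clean days at sweep resolution (dt = 0.05 h)."""
    return make_square_wave(period=24.0, day_fraction=0.5,
                            t_end=30 * 24.0 + 0.05, dt=0.05)


@pytest.fixture(scope="session")
def cycle_geometry():
    return ClockGeometry.limit_cycle(R=1.0, L=0.1)


@pytest.fixture(scope="session")
def point_geometry():
    return ClockGeometry.point_attractor(L=0.1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
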
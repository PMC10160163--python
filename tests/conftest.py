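import numpy as np
import pytest

from cineflow.phantom import PhantomConfig, make_phantom
from cineflow.types import AcquisitionMeta


@pytest.fixture(scope="session")
def meta():
    return AcquisitionMeta(
        pixel_spacing=(1.25, 1.25), frame_interval=0.04, heart_rate=60.0, n_phases=30
    )


@pytest.fixture(scope="session")
def tiny_config():
    """A 16x16, 12-phase phantom small enough for per-test training runs."""
    return PhantomConfig(
        grid=(16, 16),
        n_phases=12,
        vortex_peak_speed=3.0,
        vortex_baseline=0.6,
        e_peak_speed=2.5,
        a_peak_speed=1.8,
        gap_half_width=1.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return make_phantom(tiny_config)


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
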
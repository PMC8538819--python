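import numpy as np
import pytest

from mnpsteer.actuation import ActuationScheme, CoilPair
from mnpsteer.forces import FluidMedium, Particle


@pytest.fixture(scope="session")
def coils():
    return CoilPair()


@pytest.fixture()
def medium():
    return FluidMedium()


@pytest.fixture()
def static_scheme():
    return ActuationScheme(scheme="static", H=3.0, h=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_particle(rng, pid=0, scale=2e-6, moment_scale=1e-13):
    return Particle(
        id=pid,
        position=rng.normal(0.0, scale, 3),
        velocity=rng.normal(0.0, 1e-4, 3),
        radius=rng.uniform(0.3e-6, 0.8e-6),
        density=rng.uniform(1500.0, 6000.0),
        moment=rng.normal(0.0, moment_scale, 3),
    )
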
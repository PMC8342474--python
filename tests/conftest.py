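import numpy as np
import pytest

from spholo import AcquisitionConfig, ComplexImage, HadamardPlan


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def plan8():
    return HadamardPlan(8)


@pytest.fixture(scope="session")
def plan16():
    return HadamardPlan(16)


@pytest.fixture
def noise_free():
    return AcquisitionConfig(noise_rel=0.0)


def random_object(side, rng, max_amp=1.0):
    """A random complex object with amplitude in [0, max_amp]."""
    return ComplexImage(
        amplitude=max_amp * rng.uniform(0.0, 1.0, (side, side)),
        phase=rng.uniform(-np.pi, np.pi, (side, side)),
    )
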
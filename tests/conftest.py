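import numpy as np
import pytest
from hypothesis import settings

from echocorrect import (
    AcousticInterface,
    AcousticMedium,
    PhantomSpec,
    SensitivityModel,
    make_calibration_phantom,
)

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def water_tissue() -> AcousticInterface:
    """Water coupling into generic soft tissue (the default interface)."""
    return AcousticInterface()


@pytest.fixture(scope="session")
def matched_interface() -> AcousticInterface:
    m = AcousticMedium(c=1500.0, density=1000.0)
    return AcousticInterface(incident=m, transmit=m)


@pytest.fixture
def small_spec() -> PhantomSpec:
    """64 px FOV on a 129×129 grid with an integer centre pixel."""
    return PhantomSpec(fov_radius_px=64.0)


@pytest.fixture
def calibration_06(small_spec):
    """Noiseless uniform phantom under a 0.6 edge-ratio Gaussian field."""
    img, gt = make_calibration_phantom(small_spec, SensitivityModel.gaussian(0.6))
    return img, gt


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
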
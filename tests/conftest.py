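import numpy as np
import pytest

from physometry import PhantomSpec, generate_subject
from physometry.devices import DeviceProfile


@pytest.fixture(scope="session")
def small_device() -> DeviceProfile:
    """A compact test scanner: 256x256 matrix at 0.625 mm spacing (the
    coarsest supported resolution) keeps the whole phantom in view while
    staying fast."""
    return DeviceProfile(
        name="test_1T",
        field_strength=1.0,
        pixel_spacing=(0.625, 0.625),
        matrix=(256, 256),
        slice_thickness=4.0,
    )


@pytest.fixture(scope="session")
def clean_phantom(small_device):
    """Noise-free mid-adolescence phantom with its ground truth."""
    spec = PhantomSpec(age=14.0, sex="F", device=small_device, noise_sd=0.0, seed=42)
    return generate_subject(spec)


@pytest.fixture(scope="session")
def noisy_phantom(small_device):
    """Default-noise phantom with its ground truth."""
    spec = PhantomSpec(age=14.0, sex="F", device=small_device, seed=42)
    return generate_subject(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
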
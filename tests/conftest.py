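import numpy as np
import pytest

from gelcam import (
    CameraResponseModel,
    GelSceneSpec,
    IlluminationField,
    generate_pwm_series,
    series_from_images,
)

PWM_LEVELS = (100, 80, 60, 40, 20)


@pytest.fixture
def field():
    return IlluminationField()


@pytest.fixture
def ideal_camera():
    """Perfectly linear, noise-free camera: the baseline every metric scores."""
    return CameraResponseModel(gain=230.0, gamma=1.0, offset=0.0, noise_sigma=0.0, seed=0)


def make_series(gamma=1.0, noise_sigma=0.0, seed=0, gain=230.0, offset=0.0,
                levels=PWM_LEVELS, shape=(32, 128), name="cam"):
    cam = CameraResponseModel(
        gain=gain, gamma=gamma, offset=offset, noise_sigma=noise_sigma,
        seed=seed, name=name,
    )
    images = generate_pwm_series(cam, IlluminationField(), levels, shape)
    return series_from_images(images, camera=name)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def ideal_series():
    return make_series(gamma=1.0, noise_sigma=0.0)


@pytest.fixture
def gel_spec():
    return GelSceneSpec(noise_sigma=0.0)
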
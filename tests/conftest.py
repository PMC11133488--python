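import numpy as np
import pytest

from parsim.simulate import (NoiseModel, OpticsModel, PatternSet,
                             bead_scene, mixed_scene)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def optics():
    # NA 1.49 oil objective, 580 nm emission, 65 nm pixels: k_c ~ 0.334 c/px
    return OpticsModel()


@pytest.fixture
def small_scene(rng, optics):
    return mixed_scene((96, 96), rng, pixel_size=optics.pixel_size)


@pytest.fixture
def study_scene(rng, optics):
    return mixed_scene((192, 192), rng, pixel_size=optics.pixel_size)


@pytest.fixture
def beads(rng, optics):
    return bead_scene((128, 128), 60, rng, amplitude=20.0,
                      pixel_size=optics.pixel_size)


@pytest.fixture
def patterns():
    return PatternSet(n_angles=2, angles=(0.0, 90.0), period=3.8,
                      modulation=0.8, amplitude=50.0)


@pytest.fixture
def noise_model():
    return NoiseModel(photon_scale=1.0, read_noise_sigma=8.0,
                      baseline_offset=100.0, seed=7)
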
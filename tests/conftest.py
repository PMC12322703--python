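import numpy as np
import pytest

from licodet.scenes import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    return SceneSpec(image_size=160, plants_per_image=(2, 5), plant_radius=(8, 60),
                     weed_density=8, occlusion_prob=0.3, seed=11)


@pytest.fixture(scope="session")
def sample_scene(small_spec):
    return generate_scene(small_spec, 0)
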
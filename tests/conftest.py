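import numpy as np
import pytest

from deblurseg import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_scene():
    """64x64 field scene layout used by the scaled-down experiments."""
    return synth.SceneSpec(height=64, width=64, n_crops=1, n_weeds=2,
                           crop_radius=(6, 10), weed_radius=(3, 5))


@pytest.fixture(scope="session")
def tiny_blur():
    return synth.BlurParams(kernel_size=13)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_scene, tiny_blur):
    """Eight blurred/sharp/label training triples, held fixed per session."""
    return synth.generate_pairs(8, tiny_scene, tiny_blur, seed=100)


@pytest.fixture(scope="session")
def tiny_test_pairs(tiny_scene, tiny_blur):
    return synth.generate_pairs(4, tiny_scene, tiny_blur, seed=200)
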
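import numpy as np
import pytest

from residuemap.multiscale import build_feature_stack
from residuemap.synthetic_scene import (
    SceneSpec,
    generate_sample_set,
    generate_scene,
    overlap_scene_spec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def overlap_scene():
    """256x256 scene where classes overlap spectrally but differ in texture."""
    image, truth = generate_scene(overlap_scene_spec(size=(256, 256), seed=11))
    return image, truth


@pytest.fixture(scope="session")
def overlap_stack(overlap_scene):
    image, _ = overlap_scene
    return build_feature_stack(image)


@pytest.fixture(scope="session")
def overlap_samples(overlap_scene):
    _, truth = overlap_scene
    return generate_sample_set(truth, 500, seed=11)


@pytest.fixture(scope="session")
def default_scene():
    """Small instance of the default scene recipe."""
    image, truth = generate_scene(SceneSpec(size=(128, 128), seed=3))
    return image, truth
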
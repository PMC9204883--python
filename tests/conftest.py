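import numpy as np
import pytest

from truss_seg.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def clean_config():
    """Default-regime scenes with the depth sensor always succeeding."""
    return SceneConfig(defocus_prob=0.0, rng_seed=1)


@pytest.fixture(scope="session")
def small_clean_config():
    """64-pixel scenes for fast pipeline tests."""
    return SceneConfig(image_size=64, defocus_prob=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def clean_scene(clean_config):
    return generate_scene(clean_config, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
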
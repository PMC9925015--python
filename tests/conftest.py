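import numpy as np
import pytest

from eyespot.synthetic import SceneParams, generate_eyespot_crop, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic mid-density scene shared across read-only tests."""
    return generate_scene(SceneParams(seed=7))


@pytest.fixture(scope="session")
def default_crop():
    """One deterministic eyespot crop (image, mask, gt)."""
    return generate_eyespot_crop(SceneParams(n_elements=(1, 1), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
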
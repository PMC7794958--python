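import numpy as np
import pytest
from skimage.draw import disk

from cucurbita.scene import SceneConfig, render_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Mid-sized scene without occlusion or touching pairs."""
    cfg = SceneConfig(shape=(900, 900), n_fruits=60, seed=42)
    return render_scene(cfg)


@pytest.fixture(scope="session")
def hard_scene():
    """Scene with shading, overexposure, occlusion and touching pairs."""
    cfg = SceneConfig(shape=(900, 900), n_fruits=60, fraction_touching=0.1,
                      fraction_occluded=0.1, illumination_split=True, seed=7)
    return render_scene(cfg)


def make_disk_mask(shape, centers, radius):
    mask = np.zeros(shape, np.uint8)
    for rc in centers:
        rr, cc = disk(rc, radius, shape=shape)
        mask[rr, cc] = 1
    return mask


@pytest.fixture
def disk_mask_factory():
    return make_disk_mask
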
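import numpy as np
import pytest

from ncfratio import SceneSpec, box_background, build_region_set, make_wedge_scene

# distant background box used across tests: top-left corner, clear of the
# default centred disc
BG_BOX = (8, 8, 48, 48)


@pytest.fixture(scope="session")
def noise_free_scene():
    return make_wedge_scene(SceneSpec(noise_sigma1=0.0, noise_sigma2=0.0))


@pytest.fixture(scope="session")
def noisy_scene():
    return make_wedge_scene(SceneSpec(seed=0))


def scene_regions(scene, depth_in=10, depth_out=50):
    return build_region_set(
        scene.truth.mask_true,
        depth_in=depth_in,
        depth_out=depth_out,
        bg_box=BG_BOX,
    )


def scene_backgrounds(scene):
    bg1, _ = box_background(scene.img1, BG_BOX)
    bg2, _ = box_background(scene.img2, BG_BOX)
    return bg1, bg2


@pytest.fixture(scope="session")
def noisy_regions(noisy_scene):
    return scene_regions(noisy_scene)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
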
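import numpy as np
import pytest

from ropmap.synthetic import GeneratorConfig, default_field_plan, generate_eye, render_fields
from ropmap.transforms import SimilarityTransform


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def rendered_eye(default_config):
    """One fully rendered 5-field eye, shared across tests (read-only)."""
    eye = generate_eye(default_config, 42)
    return render_fields(eye, default_field_plan(eye, default_config))


@pytest.fixture(scope="session")
def big_scene(default_config):
    """A large rendered panorama scene for carving registration test pairs."""
    from ropmap.synthetic import render_scene

    eye = generate_eye(default_config, 7)
    scene, origin = render_scene(eye, (-400, -400, 1100, 1000))
    return scene


def make_registration_pair(scene, t_scene: SimilarityTransform, window=(640, 480), offset=(380, 300)):
    """Carve a (fixed, moving, true_transform) triple out of a big scene.

    fixed(x) = scene(x + o); moving(x) = scene(T_s(x + o)); the transform
    mapping moving coordinates into the fixed frame is then
    translate(-o) o T_s o translate(o).
    """
    from skimage import transform as sktf

    w, h = window
    ox, oy = offset
    fixed = scene[oy:oy + h, ox:ox + w]
    M = t_scene.matrix.copy()
    warped = sktf.warp(scene.astype(float), sktf.SimilarityTransform(matrix=M), output_shape=scene.shape, order=1)
    moving = np.clip(warped[oy:oy + h, ox:ox + w], 0, 255).astype(np.uint8)
    shift = SimilarityTransform(translation=(ox, oy))
    unshift = SimilarityTransform(translation=(-ox, -oy))
    true = unshift.compose(t_scene).compose(shift)
    return fixed, moving, true
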
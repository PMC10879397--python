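import numpy as np
import pytest

from cbtools.synthetic import SceneSpec, generate_patch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """One mid-size scene with CBs and clutter, shared read-only."""
    spec = SceneSpec(n_cb=5, n_other=3, image_size=320, seed=7)
    patch, boxes, cells = generate_patch(spec, return_cells=True)
    return spec, patch, boxes, cells


def make_box(cx, cy, w, h, class_id=0, confidence=None):
    from cbtools.tiles import Box

    return Box(class_id=class_id, cx=cx, cy=cy, w=w, h=h, confidence=confidence)
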
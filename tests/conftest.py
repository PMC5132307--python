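import numpy as np
import pytest

from beadassay.synthgen import SceneParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_scene(**overrides) -> SceneParams:
    """A fast-to-render scene used throughout the suite: 3 short worms in a
    256 px frame, every worm a responder unless overridden."""
    defaults = dict(
        image_height=256,
        image_width=256,
        n_worms=3,
        worm_width=7,
        worm_length_range=(60, 100),
        responder_fraction=1.0,
        beads_per_responder_range=(10, 25),
        stray_bead_rate=1.0,
        seed=0,
    )
    defaults.update(overrides)
    return SceneParams(**defaults)


@pytest.fixture
def small_scene_params():
    return small_scene
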
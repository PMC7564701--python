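import numpy as np
import pytest

from flygroom.synthetic import SyntheticScene, render_video


@pytest.fixture(scope="session")
def head_scene_frames():
    """A short scene with one head-grooming bout, plus its truth."""
    scene = SyntheticScene(n_frames=40, schedule=(("head", 0, 39),), seed=3)
    frames, truth = render_video(scene)
    return scene, frames, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
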
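import numpy as np
import pytest

from nk3d.projection import ImageStack
from nk3d.synthetic_data import SceneConfig, simulate_trajectories, render_stack


# A compact field of view used by the image-level tests: 333 µm box,
# 16 z-planes at 10 µm, 11 frames at 30 s.
SMALL_BOX = dict(volume=333.0 ** 2 * 160.0, depth=160.0)


@pytest.fixture(scope="session")
def small_scene():
    """Rendered scene with 25 NK + 3 K562 cells and its ground truth."""
    cfg = SceneConfig(n_nk=25, n_k562=3, seed=7, **SMALL_BOX)
    truth = simulate_trajectories(cfg)
    stack = render_stack(truth)
    return truth, stack


@pytest.fixture()
def noiseless_stack():
    """Tiny uniform stack for projection contract tests."""
    data = np.full((2, 4, 8, 8), 100.0, dtype=np.float32)
    return ImageStack(data=data, pixel_size=1.0, z_step=10.0, frame_interval=30.0)
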
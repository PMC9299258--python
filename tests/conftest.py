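import numpy as np
import pytest

from rgbdssd.synthetic_scenes import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneConfig(), seed=42)


@pytest.fixture(scope="session")
def small_scenes():
    """A handful of quick-to-render scenes for pipeline-level tests."""
    cfg = SceneConfig(image_width=160, image_height=128,
                      fruit_radius=(14, 28), n_fruits=(2, 4))
    return [generate_scene(cfg, seed) for seed in (1, 2, 3, 4)]


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of scalar f() w.r.t. array x in place."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g
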
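import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenes160():
    """A handful of default-condition synthetic scenes, shared per session."""
    from cattledet.synthetic import generate_synthetic_scene

    g = np.random.default_rng(7)
    return [generate_synthetic_scene(g, 3, 0.3, (160, 160), f"s{i}") for i in range(6)]


def random_xyxy(rng, n, lo=0.0, hi=100.0, min_side=1.0):
    """n random valid xyxy boxes."""
    x1 = rng.uniform(lo, hi - min_side, n)
    y1 = rng.uniform(lo, hi - min_side, n)
    w = rng.uniform(min_side, hi - x1)
    h = rng.uniform(min_side, hi - y1)
    return np.stack([x1, y1, x1 + w, y1 + h], axis=1)
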
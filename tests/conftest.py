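import numpy as np
import pytest

from peelnet.data import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scenes():
    """Eight deterministic 128x128 annotated scenes."""
    return [generate_scene(SceneSpec(), seed) for seed in range(8)]


def random_box(rng, lo=0.0, hi=100.0, min_side=1.0):
    x1, y1 = rng.uniform(lo, hi - min_side, 2)
    w, h = rng.uniform(min_side, hi - max(x1, y1), 2)
    return np.array([x1, y1, x1 + w, y1 + h])
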
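import numpy as np
import pytest

from coilmask import synthetic


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 256x256 scene with its ground truth."""
    spec = synthetic.random_scene_spec(np.random.default_rng(42))
    img, mask, meta = synthetic.generate_scene(spec)
    return img, mask, meta, spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng: np.random.Generator, shape=(48, 48), n_blobs=3) -> np.ndarray:
    """Union of random disks; occasionally multiple components. Test helper."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(5, h - 5), rng.uniform(5, w - 5)
        r = rng.uniform(3, 9)
        mask |= (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r**2
    return mask
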
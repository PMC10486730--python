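import numpy as np
import pytest

from bonetex.roi import TrabecularROI
from bonetex.synthetic import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20230828)


@pytest.fixture
def small_phantom_cfg():
    """A compact phantom, fast enough for per-test use."""
    return PhantomConfig(image_size=48, seed=7)


def make_roi(image, mask=None):
    """Wrap an arbitrary grid (optionally with a mask) as a TrabecularROI."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones_like(image, dtype=bool)
    ys, xs = np.nonzero(mask)
    center = (float(ys.mean()), float(xs.mean()))
    return TrabecularROI(mask=mask, image=image, center=center,
                         radius=float(max(image.shape)))


@pytest.fixture
def roi_factory():
    return make_roi
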
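import numpy as np
import pytest

from apoptoquant import CalibratedImage


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def calibrated():
    """Factory: wrap a 2D array as a CalibratedImage (default 0.5 um/px)."""

    def make(pixels, pixel_size_um=0.5, **kwargs):
        return CalibratedImage(np.asarray(pixels, dtype=float), pixel_size_um, **kwargs)

    return make
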
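import numpy as np
import pytest

from rfrad.feature_maps import FeatureMap
from rfrad.rf_core import RFFrame, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_frame(rng):
    """A 256 x 8 white-noise RF frame."""
    return RFFrame(rng.normal(0, 1, (256, 8)))


@pytest.fixture
def rect_roi():
    """A 200 x 6 rectangular ROI inside a 256 x 8 frame."""
    mask = np.zeros((256, 8), dtype=bool)
    mask[20:220, 1:7] = True
    return ROIMask(mask)


@pytest.fixture
def random_map(rng):
    """A fully valid random feature map for radiomics tests."""
    v = rng.normal(0, 1, (30, 12))
    return FeatureMap(values=v, valid=np.ones_like(v, dtype=bool), kind="DEA")
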
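import numpy as np
import pytest

from neurodrain.volumes import BinaryMask, ProbabilityVolume


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return ProbabilityVolume(np.asarray(data, float), aff)


def make_mask(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return BinaryMask(np.asarray(data, bool), aff)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
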
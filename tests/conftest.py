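import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radagree.image_model import ImageVolume, Modality, ROIMask
from radagree.synthetic import fixture_phantoms


@pytest.fixture(scope="session")
def phantoms():
    return fixture_phantoms()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(data, spacing=(1, 1, 1), origin=(0, 0, 0), modality=Modality.CT):
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin, modality)


def make_mask(data, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return ROIMask(np.asarray(data), spacing, origin)


@pytest.fixture()
def random_volume_mask(rng):
    """A 9x9x9 noisy volume with a blobby mask, for generic checks."""
    data = rng.normal(50, 10, size=(9, 9, 9))
    i, j, k = np.indices((9, 9, 9))
    mask = (i - 4) ** 2 + (j - 4) ** 2 + (k - 4) ** 2 <= 12
    return make_volume(data), make_mask(mask)
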
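import numpy as np
import pytest

from radsel.io import BinaryMask, SUVolume
from radsel.feature_extraction import QuantizedVolume, UNMASKED, quantize


@pytest.fixture
def uniform_region():
    """2x2x2 region of SUV 10 inside a 4x4x4 grid, spacing 4x4x2 mm."""
    values = np.zeros((4, 4, 4))
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1:3, 1:3, 1:3] = True
    values[mask] = 10.0
    spacing = (4.0, 4.0, 2.0)
    return SUVolume(values, spacing), BinaryMask(mask, spacing)


def random_region(seed: int, shape=(4, 4, 4), n_levels=5, spacing=(1.0, 1.0, 1.0),
                  mask_fraction=1.0):
    """Random quantized region: levels drawn uniformly from 0..n_levels-1."""
    rng = np.random.default_rng(seed)
    suv = rng.integers(0, n_levels, size=shape) / 0.5  # levels exact at D=0.5
    mask = rng.random(shape) < mask_fraction
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    vol = SUVolume(suv.astype(float), spacing)
    m = BinaryMask(mask, spacing)
    return vol, m, quantize(vol, m, 0.5)


@pytest.fixture
def random_region_factory():
    return random_region
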
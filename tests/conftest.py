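import numpy as np
import pytest

from osteoseg.phantom import PhantomConfig, generate_phantom
from osteoseg.volume_io import LabelMask, ScanVolume


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic easy phantom (16x64x64, u16)."""
    return generate_phantom(PhantomConfig(seed=11))


@pytest.fixture(scope="session")
def micro_pool():
    """Four tiny scan/mask pairs (4x16x16) for fast fit/predict tests."""
    pool = []
    for i in range(4):
        cfg = PhantomConfig(shape=(4, 16, 16), cortex_radius_px=(5, 6),
                            cortex_thickness_px=(2, 2), pore_radius_px=(1, 2),
                            seed=200 + i)
        pool.append(generate_phantom(cfg))
    return pool


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_masks():
    """A 4x4 single-slice mask pair with hand-countable overlap.

    ref has 6 bone voxels, pred has 4, 2 shared -> bone IoU 2/8.
    """
    ref = np.zeros((1, 4, 4), dtype=np.uint8)
    pred = np.zeros((1, 4, 4), dtype=np.uint8)
    ref[0, 0, 0:3] = 1
    ref[0, 1, 0:3] = 1
    pred[0, 1, 1:3] = 1
    pred[0, 2, 1:3] = 1
    return (LabelMask(scan_id="ref", labels=ref),
            LabelMask(scan_id="pred", labels=pred))


def make_volume(arr, scan_id="s", bit_depth=None):
    arr = np.asarray(arr)
    if bit_depth is None:
        bit_depth = {"uint8": "u8", "uint16": "u16"}.get(arr.dtype.name, "float")
    return ScanVolume(scan_id=scan_id, voxels=arr, bit_depth=bit_depth)
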
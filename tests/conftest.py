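import numpy as np
import pytest
from hypothesis import settings

from qfuzzy.cells import SegmentedCell

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def disk(shape, center, radius):
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture
def disk_cell():
    """Disk nucleus (r=8) inside a disk cytoplasm (r=20) with flat shading."""
    shape = (64, 64)
    cyto = disk(shape, (32, 32), 20)
    nuc = disk(shape, (32, 32), 8)
    mask = np.zeros(shape, dtype=int)
    mask[cyto] = 1
    mask[nuc] = 2
    intensity = np.full(shape, 220.0)
    intensity[cyto] = 160.0
    intensity[nuc] = 90.0
    return SegmentedCell(intensity=intensity, mask=mask)


@pytest.fixture
def textured_cell():
    """Like disk_cell but with seeded Gaussian texture on top."""
    shape = (64, 64)
    cyto = disk(shape, (32, 32), 20)
    nuc = disk(shape, (30, 33), 8)
    mask = np.zeros(shape, dtype=int)
    mask[cyto] = 1
    mask[nuc] = 2
    rng = np.random.default_rng(7)
    intensity = np.clip(
        np.where(nuc, 90.0, np.where(cyto, 160.0, 220.0)) + rng.normal(0, 12, shape),
        0, 255,
    ).round()
    return SegmentedCell(intensity=intensity, mask=mask)
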
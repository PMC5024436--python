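import numpy as np
import pytest

from somapeaks.types import RegionPointSet, VolumeStack


@pytest.fixture
def rng():
    return np.random.default_rng(20231109)


@pytest.fixture
def random_region(rng):
    """A 200-point region on a 2-um lattice with Poisson-like intensities."""

    def make(n=200, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        # distinct lattice sites inside a 20^3 box
        sites = r.choice(20**3, size=n, replace=False)
        idx = np.stack(np.unravel_index(sites, (20, 20, 20)), axis=1)
        vox = np.array([2.0, 2.0, 2.0])
        return RegionPointSet(
            indices=idx,
            positions_um=(idx + 0.5) * vox,
            intensities=r.poisson(150, size=n).astype(float),
            region_id=1,
        )

    return make


@pytest.fixture
def flat_stack():
    """A constant background stack (no somas)."""
    return VolumeStack(np.full((30, 30, 30), 100, dtype=np.uint16), (2.0, 2.0, 2.0))
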
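import numpy as np
import pytest

from ventpack.phantom import make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_case():
    """A mid-sized phantom with planted balls, scattered unit defects and
    realistic ventilated texture, reused by several module tests."""
    return make_phantom(
        defect_inventory=[(7, 1), (5, 2), (3, 3), (1, 60)],
        smoothness_vox=2.5,
        heterogeneity=0.3,
        seed=7,
    )


def random_levels(rng, shape=(6, 6, 3), Ng=5, p_outside=0.2):
    """Random discretized ROI: levels 1..Ng with some voxels outside."""
    lev = rng.integers(1, Ng + 1, size=shape).astype(np.int32)
    lev[rng.random(shape) < p_outside] = 0
    if not (lev > 0).any():
        lev[0, 0, 0] = 1
    return lev
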
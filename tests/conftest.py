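import numpy as np
import pytest

from petfactor.volume import LesionMask, PETVolume


def random_lesion(seed: int, shape=(5, 5, 5), density: float = 0.7,
                  max_suv: float = 1.0, spacing=(1.0, 1.0, 1.0)):
    """Small random SUV grid + random mask; SUVs in [0, max_suv)."""
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=shape) < density
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    vals = rng.uniform(0.0, max_suv, size=shape)
    return PETVolume(vals, spacing), LesionMask(mask)


@pytest.fixture
def lesion_factory():
    return random_lesion


@pytest.fixture
def uniform_volume():
    """16^3 grid of constant SUV 5 at 4-mm spacing."""
    return PETVolume(np.full((16, 16, 16), 5.0), (4.0, 4.0, 4.0))
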
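"""Fixed-bin-size grey-level discretization of SUV values.

SUV is an absolute, calibrated scale, so bins are anchored at 0 and have a
fixed width (default 0.25 SUV):

    level(x) = floor(x / bin_size) + 1        for x >= 0

The number of grey levels G is the maximum level observed inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volume import LesionMask, PETVolume

DEFAULT_BIN_SIZE = 0.25


@dataclass
class DiscretizedVolume:
    """Integer grey levels (1..G inside the mask, 0 outside)."""

    grey_levels: np.ndarray
    mask: np.ndarray
    bin_size: float
    n_levels: int

    def levels_in_mask(self) -> np.ndarray:
        return self.grey_levels[self.mask]


def discretize(volume: PETVolume, mask: LesionMask,
               bin_size: float = DEFAULT_BIN_SIZE) -> DiscretizedVolume:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    m = mask.support
    if not m.any():
        raise ValueError("mask is empty")
    vals = volume.values
    if np.any(vals[m] < 0):
        raise ValueError("negative SUVs inside the mask")
    levels = np.zeros(vals.shape, dtype=np.int64)
    levels[m] = np.floor(vals[m] / bin_size).astype(np.int64) + 1
    return DiscretizedVolume(
        grey_levels=levels,
        mask=m,
        bin_size=float(bin_size),
        n_levels=int(levels[m].max()),
    )
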
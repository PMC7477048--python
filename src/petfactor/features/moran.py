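"""Moran's I spatial autocorrelation of SUV over the lesion.

Weights are inverse Euclidean distances between voxel centres.  The double
sum is O(n^2); masks larger than ``max_voxels`` are uniformly subsampled
with a seeded generator, which keeps the statistic unbiased while bounding
cost.
"""

from __future__ import annotations

import numpy as np

from ..volume import LesionMask, PETVolume


def morans_i(volume: PETVolume, mask: LesionMask,
             max_voxels: int = 2000, seed: int = 0) -> float:
    coords = np.argwhere(mask.support).astype(float) * np.asarray(volume.spacing_mm)
    x = volume.values[mask.support].astype(float)
    n = x.size
    if n < 2:
        raise ValueError("Moran's I needs at least 2 voxels")
    if n > max_voxels:
        idx = np.random.default_rng(seed).choice(n, size=max_voxels, replace=False)
        coords, x = coords[idx], x[idx]
        n = max_voxels
    dev = x - x.mean()
    denom = np.sum(dev ** 2)
    if denom == 0:
        return np.nan  # constant intensities: undefined
    d = np.sqrt(np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    num = dev @ w @ dev
    return float((n / w.sum()) * (num / denom))
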
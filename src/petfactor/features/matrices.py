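"""Texture counting matrices: GLCM, GLRLM, GLSZM, GLDZM, NGTDM, NGLDM.

All matrices are built in 3D on the discretized grey levels (1..G inside the
mask, 0 outside).  Conventions:

* GLCM / GLRLM: the 13 unique 3D directions at Chebyshev distance 1; the
  GLCM is symmetrized (each pair counted in both orders).
* GLSZM / GLDZM: zones are 26-connected sets of equal grey level; the GLDZM
  zone distance is the minimum over the zone of the Chebyshev distance (in
  voxels) to the nearest non-mask voxel, with the ROI edge at distance 1.
* NGTDM / NGLDM: 26-voxel neighbourhood; NGLDM dependence coarseness
  parameter alpha = 0 and the dependence count includes the centre voxel
  (so it ranges 1..27).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedVolume

#: The 13 unique direction vectors of the 26-neighbourhood (one per
#: antipodal pair, first non-zero component positive).
DIRECTIONS_13: list[tuple[int, int, int]] = [
    d for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TextureMatrices:
    glcm: list[np.ndarray]        # per direction, (G, G) symmetric counts
    glrlm: list[np.ndarray]       # per direction, (G, max_run) counts
    glszm: np.ndarray             # (G, max_zone_size) counts
    gldzm: np.ndarray             # (G, max_zone_distance) counts
    ngtdm_n: np.ndarray           # (G,) voxel counts per level
    ngtdm_s: np.ndarray           # (G,) summed |level - neighbourhood mean|
    ngldm: np.ndarray             # (G, 27) dependence-count counts
    n_levels: int
    n_voxels: int
    directions: list[tuple[int, int, int]]


def _crop(lev: np.ndarray) -> np.ndarray:
    """Crop to the mask bounding box (levels are 0 outside the mask)."""
    idx = np.argwhere(lev > 0)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return lev[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def _pair_slices(shape, d):
    """Slices (sl_a, sl_b) so that a[sl_a] and a[sl_b] are voxels p and p+d."""
    sl_a, sl_b = [], []
    for n, step in zip(shape, d):
        if step == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        else:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
    return tuple(sl_a), tuple(sl_b)


def glcm_direction(lev: np.ndarray, d: tuple[int, int, int], G: int) -> np.ndarray:
    sl_a, sl_b = _pair_slices(lev.shape, d)
    va, vb = lev[sl_a], lev[sl_b]
    valid = (va > 0) & (vb > 0)
    m = np.zeros((G, G))
    np.add.at(m, (va[valid] - 1, vb[valid] - 1), 1.0)
    return m + m.T


def glrlm_direction(lev: np.ndarray, d: tuple[int, int, int], G: int) -> np.ndarray:
    shape = lev.shape
    max_len = max(shape)
    m = np.zeros((G, max_len))
    # run starts: in-mask voxels whose predecessor along d differs (or is out of grid)
    prev = np.full(shape, -1, dtype=lev.dtype)
    sl_a, sl_b = _pair_slices(shape, d)
    prev[sl_b] = lev[sl_a]
    starts = np.argwhere((lev > 0) & (prev != lev))
    dv = np.asarray(d)
    for p in starts:
        g = lev[tuple(p)]
        length = 1
        q = p + dv
        while np.all(q >= 0) and np.all(q < shape) and lev[tuple(q)] == g:
            length += 1
            q = q + dv
        m[g - 1, length - 1] += 1.0
    return m


def _zones(lev: np.ndarray, G: int):
    """Yield (grey level, zone label array, zone sizes) per present level."""
    for g in range(1, G + 1):
        binary = lev == g
        if not binary.any():
            continue
        labels, k = ndimage.label(binary, structure=_STRUCT_26)
        if k == 0:
            continue
        yield g, labels, k


def glszm_matrix(lev: np.ndarray, G: int) -> np.ndarray:
    n_vox = int((lev > 0).sum())
    m = np.zeros((G, n_vox))
    for g, labels, k in _zones(lev, G):
        sizes = np.bincount(labels.ravel())[1:]
        for s in sizes:
            m[g - 1, s - 1] += 1.0
    nz = np.argwhere(m.any(axis=0))
    width = int(nz.max()) + 1 if nz.size else 1
    return m[:, :width]


def gldzm_matrix(lev: np.ndarray, G: int) -> np.ndarray:
    mask = lev > 0
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")[1:-1, 1:-1, 1:-1]
    max_d = int(dist.max())
    m = np.zeros((G, max(1, max_d)))
    for g, labels, k in _zones(lev, G):
        mins = ndimage.minimum(dist, labels=labels, index=np.arange(1, k + 1))
        for dz in np.atleast_1d(mins):
            m[g - 1, int(dz) - 1] += 1.0
    return m


def ngtdm_arrays(lev: np.ndarray, G: int) -> tuple[np.ndarray, np.ndarray]:
    mask = lev > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nsum = ndimage.convolve(lev.astype(float) * mask, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = mask & (ncnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbr_mean = np.where(valid, nsum / np.maximum(ncnt, 1e-300), 0.0)
    n = np.zeros(G)
    s = np.zeros(G)
    for g in range(1, G + 1):
        sel = valid & (lev == g)
        n[g - 1] = sel.sum()
        s[g - 1] = np.abs(g - nbr_mean[sel]).sum()
    return n, s


def ngldm_matrix(lev: np.ndarray, G: int, alpha: int = 0) -> np.ndarray:
    mask = lev > 0
    dep = np.zeros(lev.shape, dtype=np.int64)
    shape = lev.shape
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        sl_a, sl_b = _pair_slices(shape, d)
        ok = mask[sl_a] & mask[sl_b] & (np.abs(lev[sl_a] - lev[sl_b]) <= alpha)
        dep[sl_a] += ok
    j = dep + 1  # dependence count including the centre voxel: 1..27
    m = np.zeros((G, 27))
    np.add.at(m, (lev[mask] - 1, j[mask] - 1), 1.0)
    return m


def build_matrices(discretized: DiscretizedVolume) -> TextureMatrices:
    """Build all six texture matrix families from a discretized lesion."""
    lev = _crop(discretized.grey_levels)
    G = discretized.n_levels
    n_vox = int((lev > 0).sum())
    ngtdm_n, ngtdm_s = ngtdm_arrays(lev, G)
    return TextureMatrices(
        glcm=[glcm_direction(lev, d, G) for d in DIRECTIONS_13],
        glrlm=[glrlm_direction(lev, d, G) for d in DIRECTIONS_13],
        glszm=glszm_matrix(lev, G),
        gldzm=gldzm_matrix(lev, G),
        ngtdm_n=ngtdm_n,
        ngtdm_s=ngtdm_s,
        ngldm=ngldm_matrix(lev, G),
        n_levels=G,
        n_voxels=n_vox,
        directions=list(DIRECTIONS_13),
    )
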
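"""Adaptive lesion delineation and first-order SUV metrics.

The delineation follows the background-adapted 50%-of-SUVpeak isocontour used
for FDG-PET head-and-neck tumours: the threshold is

    T = bg + 0.5 * (SUVpeak - bg)

where SUVpeak is the highest mean uptake inside any 1-mL sphere centred on a
tumour voxel, and bg is the local background SUV.  The mask is the largest
26-connected supra-threshold component containing the seed; SUVpeak and the
mask are iterated to a fixed point.  Lesions below 4.2 mL (three times a
6.75-mm FWHM point-spread function) are rejected to limit partial-volume bias.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage

from .volume import MM3_PER_ML, FirstOrderMetrics, LesionMask, PETVolume

logger = logging.getLogger(__name__)

#: Radius (mm) of a 1-mL sphere: (3/(4*pi) * 1000 mm^3)^(1/3)
SPHERE_1ML_RADIUS_MM = (3.0 / (4.0 * np.pi) * MM3_PER_ML) ** (1.0 / 3.0)

#: Minimum acceptable lesion volume (mL)
MIN_LESION_ML = 4.2


class DelineationError(RuntimeError):
    """Raised when no valid lesion mask can be produced."""


class VolumeTooSmallError(ValueError):
    """Raised when a delineated lesion fails the minimum-volume filter."""


def _sphere_footprint(spacing_mm, radius_mm: float) -> np.ndarray:
    """Boolean kernel of voxels whose centres lie within ``radius_mm``."""
    half = [int(np.floor(radius_mm / s)) for s in spacing_mm]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)], indexing="ij"
    )
    dist2 = sum(g ** 2 for g in grids)
    return dist2 <= radius_mm ** 2 + 1e-9


def sphere_mean_map(volume: PETVolume, volume_ml: float = 1.0) -> np.ndarray:
    """Mean SUV inside a sphere of ``volume_ml`` centred on each voxel.

    Near the grid edge the mean runs over the in-grid part of the sphere.
    Sphere membership is decided by voxel-centre distance.
    """
    radius = (3.0 * volume_ml * MM3_PER_ML / (4.0 * np.pi)) ** (1.0 / 3.0)
    kernel = _sphere_footprint(volume.spacing_mm, radius)
    if any(k > s for k, s in zip(kernel.shape, volume.shape)):
        raise ValueError(
            f"{volume_ml}-mL sphere kernel {kernel.shape} exceeds grid {volume.shape}"
        )
    k = kernel.astype(float)
    sums = ndimage.convolve(volume.values, k, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(volume.values), k, mode="constant", cval=0.0)
    return sums / counts


def compute_suvpeak(volume: PETVolume, search_region: LesionMask,
                    volume_ml: float = 1.0) -> float:
    """SUVpeak: highest 1-mL sphere-mean SUV over all voxels of the region."""
    if search_region.n_voxels == 0:
        raise ValueError("search region is empty")
    peak_map = sphere_mean_map(volume, volume_ml)
    return float(peak_map[search_region.support].max())


def estimate_background(volume: PETVolume, mask: LesionMask,
                        gap_voxels: int = 2, shell_voxels: int = 3) -> float:
    """Mean SUV in a shell around the mask (default: 3 voxels thick, starting
    2 voxels outside), a pragmatic local-background estimate."""
    inner = ndimage.binary_dilation(mask.support, iterations=gap_voxels)
    outer = ndimage.binary_dilation(inner, iterations=shell_voxels)
    shell = outer & ~inner
    if not shell.any():
        raise DelineationError("background shell is empty (mask fills the grid)")
    return float(volume.values[shell].mean())


def _seed_component(above: np.ndarray, seed: tuple[int, int, int]) -> np.ndarray | None:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, _ = ndimage.label(above, structure=structure)
    lab = labels[seed]
    if lab == 0:
        return None
    return labels == lab


def delineate(volume: PETVolume, seed_point, background_estimate: float | None = None,
              max_iter: int = 10) -> LesionMask:
    """Background-adapted 50%-SUVpeak isocontour around a seed voxel.

    ``background_estimate`` fixed by the caller, or re-estimated from a shell
    around the evolving mask when None.  The SUVpeak search region and the
    mask are iterated to a fixed point (at most ``max_iter`` rounds).
    """
    seed = tuple(int(c) for c in seed_point)
    peak_map = sphere_mean_map(volume)
    suv_peak = float(peak_map[seed])

    mask_arr: np.ndarray | None = None
    for _ in range(max_iter):
        if background_estimate is not None:
            bg = float(background_estimate)
        elif mask_arr is not None:
            bg = estimate_background(volume, LesionMask(mask_arr))
        else:
            bg = 0.0
        threshold = bg + 0.5 * (suv_peak - bg)
        component = _seed_component(volume.values >= threshold, seed)
        if component is None:
            if mask_arr is None:
                raise DelineationError(
                    f"seed {seed} falls below the initial threshold {threshold:.3g}"
                )
            break
        if mask_arr is not None and np.array_equal(component, mask_arr):
            return LesionMask(mask_arr)
        mask_arr = component
        suv_peak = float(peak_map[mask_arr].max())
    else:
        warnings.warn(
            f"delineation did not reach a fixed point in {max_iter} iterations; "
            "returning the last mask",
            RuntimeWarning,
        )
    if mask_arr is None or not mask_arr.any():
        raise DelineationError("delineation produced an empty mask")
    return LesionMask(mask_arr)


def passes_volume_filter(mask: LesionMask, spacing_mm, min_ml: float = MIN_LESION_ML) -> bool:
    return mask.volume_ml(spacing_mm) >= min_ml


def volume_filter(mask: LesionMask, spacing_mm, min_ml: float = MIN_LESION_ML) -> LesionMask:
    """Reject lesions smaller than ``min_ml`` (default 4.2 mL).

    Returns the mask unchanged when accepted; raises
    :class:`VolumeTooSmallError` otherwise.  The decision is logged either way.
    """
    vol = mask.volume_ml(spacing_mm)
    if vol < min_ml:
        logger.info("volume filter: REJECT %.3f mL < %.3f mL", vol, min_ml)
        raise VolumeTooSmallError(
            f"lesion volume {vol:.3f} mL is below the minimum {min_ml} mL"
        )
    logger.info("volume filter: accept %.3f mL >= %.3f mL", vol, min_ml)
    return mask


def first_order(volume: PETVolume, mask: LesionMask) -> FirstOrderMetrics:
    """SUVmax, SUVmean, SUVpeak, MATV (mL) and TLG for a delineated lesion."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    vals = volume.values[mask.support]
    return FirstOrderMetrics(
        suv_max=float(vals.max()),
        suv_mean=float(vals.mean()),
        suv_peak=compute_suvpeak(volume, mask),
        matv_ml=mask.volume_ml(volume.spacing_mm),
    )
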
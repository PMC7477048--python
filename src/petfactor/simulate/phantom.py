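"""Textured PET lesion phantoms.

A phantom is an ellipsoidal lesion on a uniform background, optionally
textured (Gaussian random field or a two-compartment necrotic core),
convolved with a separable Gaussian point-spread function (sigma =
FWHM / 2.355) and corrupted with additive Gaussian noise.  The defaults
mirror a clinical FDG-PET acquisition: 4 x 4 x 4 mm voxels and a 6.75-mm
FWHM.  The returned "true" mask is the pre-blur lesion support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..volume import LesionMask, PETVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class PhantomSpec:
    """Parameters of a synthetic lesion phantom.

    texture_model : one of ``uniform``, ``grf`` (Gaussian random field with
        ``texture_correlation_mm`` correlation length and ``texture_sd``
        amplitude) or ``necrotic_core`` (a cooler core of relative radius
        ``core_fraction`` at ``suv_core``).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    semi_axes_mm: tuple[float, float, float] = (15.0, 12.0, 10.0)
    center_mm: tuple[float, float, float] | None = None  # default: grid centre
    suv_background: float = 1.0
    suv_lesion_mean: float = 8.0
    texture_model: str = "uniform"
    texture_sd: float = 1.0
    texture_correlation_mm: float = 8.0
    suv_core: float = 2.0
    core_fraction: float = 0.5
    psf_fwhm_mm: float = 6.75
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.suv_background < 0 or self.suv_lesion_mean < 0 or self.suv_core < 0:
            raise ValueError("SUVs must be non-negative")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be strictly positive")
        if self.texture_model not in ("uniform", "grf", "necrotic_core"):
            raise ValueError(f"unknown texture model {self.texture_model!r}")


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    spacing = np.asarray(spec.voxel_size_mm)
    shape = np.asarray(spec.grid_shape)
    if spec.center_mm is None:
        center = (shape - 1) / 2.0 * spacing
    else:
        center = np.asarray(spec.center_mm, dtype=float)
    axes = np.asarray(spec.semi_axes_mm, dtype=float)
    # lesion must fit inside the grid
    lo = center - axes
    hi = center + axes
    extent = (shape - 1) * spacing
    if np.any(lo < 0) or np.any(hi > extent):
        raise ValueError(
            f"lesion (centre {center}, semi-axes {axes}) exceeds grid extent {extent}"
        )
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def _texture(spec: PhantomSpec, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pre-blur lesion intensities (SUV) on the lesion support."""
    tex = np.full(mask.shape, float(spec.suv_lesion_mean))
    if spec.texture_model == "grf":
        sigma_vox = [
            spec.texture_correlation_mm / s for s in spec.voxel_size_mm
        ]
        field = rng.standard_normal(mask.shape)
        field = ndimage.gaussian_filter(field, sigma_vox)
        sd = field[mask].std()
        if sd > 0:
            field = field / sd * spec.texture_sd
        tex = tex + field
    elif spec.texture_model == "necrotic_core":
        spacing = np.asarray(spec.voxel_size_mm)
        shape = np.asarray(spec.grid_shape)
        center = ((shape - 1) / 2.0 * spacing if spec.center_mm is None
                  else np.asarray(spec.center_mm))
        axes = np.asarray(spec.semi_axes_mm) * spec.core_fraction
        grids = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
        )
        core = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes)) <= 1.0
        tex[core] = spec.suv_core
    return np.clip(tex, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> tuple[PETVolume, LesionMask]:
    """Simulate a PET SUV volume and the true (pre-blur) lesion mask."""
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec)
    image = np.full(spec.grid_shape, float(spec.suv_background))
    tex = _texture(spec, mask, rng)
    image[mask] = tex[mask]
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.voxel_size_mm
        ]
        image = ndimage.gaussian_filter(image, sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)
    return (
        PETVolume(values=image, spacing_mm=spec.voxel_size_mm),
        LesionMask(support=mask),
    )
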
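"""Morphological (shape) features of a binary lesion mask.

Surface-based quantities (surface area, sphericity, asphericity,
compactness) use a triangle mesh from marching cubes on the 0.5 isosurface
of the padded mask; axis lengths use the principal-component decomposition
of the physical voxel-centre coordinates, with the IBSI convention
axis length = 4 * sqrt(eigenvalue).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from ..volume import MM3_PER_ML, LesionMask


def _mesh(mask: np.ndarray, spacing_mm) -> tuple[np.ndarray, np.ndarray]:
    # 1-voxel Gaussian anti-aliasing before meshing: marching cubes on the
    # raw binary mask leaves a faceted staircase surface whose area does not
    # converge to the smooth-shape value under grid refinement
    padded = np.pad(mask.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, 0.8)
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=tuple(spacing_mm)
    )
    return verts, faces

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    # divergence theorem over signed tetrahedra
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0))


def morphology_features(mask: LesionMask, spacing_mm) -> dict[str, float]:
    """Shape descriptors keyed ``morph/<name>``; degenerate values are NaN."""
    m = mask.support
    n = int(m.sum())
    if n < 1:
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing_mm, dtype=float)
    voxel_volume_ml = float(np.prod(spacing)) / MM3_PER_ML
    out: dict[str, float] = {"morph/volume_voxel_ml": n * voxel_volume_ml}

    # PCA axis lengths from physical voxel-centre coordinates
    coords = np.argwhere(m) * spacing
    if n >= 2:
        cov = np.cov(coords, rowvar=False, ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    out["morph/major_axis_length_mm"] = major
    out["morph/minor_axis_length_mm"] = minor
    out["morph/least_axis_length_mm"] = least
    out["morph/elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan
    out["morph/flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else np.nan

    try:
        verts, faces = _mesh(m, spacing)
        area_mm2 = float(measure.mesh_surface_area(verts, faces))
        vol_mm3 = _mesh_volume(verts, faces)
    except (RuntimeError, ValueError):
        area_mm2, vol_mm3 = np.nan, np.nan
    out["morph/volume_mesh_ml"] = vol_mm3 / MM3_PER_ML
    out["morph/surface_area_mm2"] = area_mm2
    if np.isfinite(area_mm2) and area_mm2 > 0 and np.isfinite(vol_mm3) and vol_mm3 > 0:
        sphericity = (36.0 * np.pi * vol_mm3 ** 2) ** (1.0 / 3.0) / area_mm2
        out["morph/sphericity"] = float(sphericity)
        out["morph/asphericity"] = float(
            (area_mm2 ** 3 / (36.0 * np.pi * vol_mm3 ** 2)) ** (1.0 / 3.0) - 1.0
        )
        out["morph/compactness1"] = float(vol_mm3 / (np.sqrt(np.pi) * area_mm2 ** 1.5))
        out["morph/compactness2"] = float(36.0 * np.pi * vol_mm3 ** 2 / area_mm2 ** 3)
        out["morph/surface_to_volume_ratio"] = float(area_mm2 / vol_mm3)
    else:
        for k in ("sphericity", "asphericity", "compactness1", "compactness2",
                  "surface_to_volume_ratio"):
            out[f"morph/{k}"] = np.nan
    return out
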
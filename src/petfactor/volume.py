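"""Core image containers: SUV volumes, binary lesion masks, first-order metrics.

SUV (standardized uptake value) is the body-weight-normalized tracer
concentration; it is unitless.  Volumes carry their physical voxel spacing in
millimetres so that every downstream quantity (MATV in mL, sphere radii,
distance weights) is computed in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MM3_PER_ML = 1000.0


@dataclass
class PETVolume:
    """A 3D grid of SUV values with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        SUV per voxel; must be finite.
    spacing_mm : tuple of float
        Voxel edge lengths in mm, one per axis; strictly positive.
    origin : tuple of float
        Physical offset of the first voxel centre (mm).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            n_bad = int(np.sum(~np.isfinite(self.values)))
            raise ValueError(f"volume contains {n_bad} non-finite voxels")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres."""
        return float(np.prod(self.spacing_mm)) / MM3_PER_ML


@dataclass
class LesionMask:
    """Binary volume of interest on the same grid as its :class:`PETVolume`."""

    support: np.ndarray
    connectivity: int = 26

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support).astype(bool)
        if self.support.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())

    def volume_ml(self, spacing_mm) -> float:
        return self.n_voxels * float(np.prod(spacing_mm)) / MM3_PER_ML


@dataclass
class FirstOrderMetrics:
    """Whole-lesion first-order SUV summary.

    TLG (total lesion glycolysis) is always the product SUVmean x MATV and is
    never stored independently of its factors.
    """

    suv_max: float
    suv_mean: float
    suv_peak: float
    matv_ml: float

    @property
    def tlg(self) -> float:
        return self.suv_mean * self.matv_ml

    def as_dict(self) -> dict[str, float]:
        return {
            "suv_max": self.suv_max,
            "suv_mean": self.suv_mean,
            "suv_peak": self.suv_peak,
            "matv_ml": self.matv_ml,
            "tlg": self.tlg,
        }
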
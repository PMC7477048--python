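"""Top-level radiomic feature extraction for a delineated lesion."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ..volume import LesionMask, PETVolume
from .discretize import DEFAULT_BIN_SIZE, discretize
from .intensity import intensity_features
from .matrices import build_matrices
from .moran import morans_i
from .morphology import morphology_features
from .texture import texture_features

logger = logging.getLogger(__name__)


@dataclass
class FeatureConfig:
    """What to extract and how.

    bin_size : fixed SUV bin width for discretization (0.25 SUV default).
    families : feature families to compute.
    moran_max_voxels / moran_seed : subsample cap for Moran's I.
    """

    bin_size: float = DEFAULT_BIN_SIZE
    families: tuple[str, ...] = (
        "morph", "stat", "ih", "ivh", "moran",
        "glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm",
    )
    aggregation: str = "averaged"  # 13-direction feature averaging
    moran_max_voxels: int = 2000
    moran_seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(
            {
                "bin_size": self.bin_size,
                "families": list(self.families),
                "aggregation": self.aggregation,
                "moran_max_voxels": self.moran_max_voxels,
                "moran_seed": self.moran_seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureVector:
    """Named feature values for one lesion; NaN marks degenerate features."""

    values: dict[str, float]
    config_hash: str
    degenerate: list[str] = field(default_factory=list)

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or sorted(self.values)
        return np.array([self.values[n] for n in names])


def extract_all(volume: PETVolume, mask: LesionMask,
                config: FeatureConfig | None = None) -> FeatureVector:
    """Extract every configured feature; deterministic for identical input."""
    config = config or FeatureConfig()
    fams = set(config.families)
    values: dict[str, float] = {}

    if "morph" in fams:
        values.update(morphology_features(mask, volume.spacing_mm))
    disc = discretize(volume, mask, config.bin_size)
    if "stat" in fams or "ih" in fams or "ivh" in fams:
        inten = intensity_features(volume, mask, disc)
        values.update(
            {k: v for k, v in inten.items() if k.split("/")[0] in fams}
        )
    if "moran" in fams:
        try:
            values["moran/morans_i"] = morans_i(
                volume, mask, config.moran_max_voxels, config.moran_seed
            )
        except ValueError:
            values["moran/morans_i"] = np.nan
    texture_fams = fams & {"glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm"}
    if texture_fams:
        mats = build_matrices(disc)
        tex = texture_features(mats)
        values.update({k: v for k, v in tex.items() if k.split("/")[0] in texture_fams})

    degenerate = sorted(k for k, v in values.items() if not np.isfinite(v))
    if degenerate:
        logger.debug("degenerate features: %s", degenerate)
    logger.info(
        "extracted %d features (%d degenerate), config %s",
        len(values), len(degenerate), config.hash(),
    )
    return FeatureVector(values=values, config_hash=config.hash(), degenerate=degenerate)
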
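"""File formats and reproducibility plumbing.

Volumes and masks are NIfTI (spacing in the affine); tables are CSV with a
header row; fitted factor models and run manifests are JSON.  A
:class:`RunManifest` records the config hash, package version, seeds and
per-artifact checksums so a run can be replayed and verified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .volume import LesionMask, PETVolume


def write_volume(path, volume: PETVolume) -> None:
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def read_volume(path) -> PETVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if np.isnan(data).any():
        raise ValueError(f"{path}: volume contains {int(np.isnan(data).sum())} NaNs")
    spacing = img.header.get_zooms()[:3]
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: missing or invalid voxel spacing {spacing}")
    origin = tuple(np.asarray(img.affine)[:3, 3].tolist())
    return PETVolume(values=data, spacing_mm=tuple(float(s) for s in spacing),
                     origin=origin)


def write_mask(path, mask: LesionMask, spacing_mm) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.support.astype(np.uint8), affine), str(path))


def read_mask(path) -> LesionMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        import warnings

        warnings.warn(f"{path}: non-binary mask (values {uniq[:5]}...), binarized at > 0")
    return LesionMask(support=data > 0)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stages: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, path) -> None:
        path = Path(path)
        self.checksums[path.name] = sha256_file(path)

    def write(self, path) -> None:
        self.finished = time.time()
        payload = dataclasses.asdict(self)
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(payload, indent=1, sort_keys=True))
        tmp.replace(path)  # atomic publish


_CONFIG_DEFAULTS = {
    "n_train": 103,
    "n_validation": 71,
    "seed": 0,
    "bin_size": 0.25,
    "redundancy_threshold": 0.95,
    "cv_folds": 5,
    "rotation": "varimax",
    "p_keep": 0.157,
    "horizon_months": 24.0,
    "stratum_mode": "threshold",
    "grid_shape": [32, 32, 32],
    "voxel_size_mm": [4.0, 4.0, 4.0],
    "psf_fwhm_mm": 6.75,
    "noise_sd": 0.1,
    "out_dir": None,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """YAML config validated against the known keys; unknown keys rejected."""
    cfg = dict(_CONFIG_DEFAULTS)
    loaded = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
    loaded.update(overrides or {})
    unknown = set(loaded) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
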
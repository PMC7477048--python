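"""Texture features computed from the counting matrices.

Directional families (GLCM, GLRLM) are computed per direction and the
feature values averaged over the 13 directions (the "averaged" aggregation).
Zone/dependence families are single-matrix.  Degenerate values (e.g. NGTDM
contrast of a single-level lesion) are returned as NaN.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrices


def _glcm_features(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:
        return {}
    p = counts / total
    G = p.shape[0]
    i = np.arange(1, G + 1)[:, None]
    j = np.arange(1, G + 1)[None, :]
    pi = p.sum(axis=1)  # row marginal
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    out = {
        "contrast": float(np.sum(p * (i - j) ** 2)),
        "dissimilarity": float(np.sum(p * np.abs(i - j))),
        "cluster_shade": float(np.sum(p * (i + j - mu_i - mu_j) ** 3)),
        "cluster_prominence": float(np.sum(p * (i + j - mu_i - mu_j) ** 4)),
        "energy": float(np.sum(p ** 2)),
        "inverse_difference": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "inverse_difference_moment": float(np.sum(p / (1.0 + (i - j) ** 2))),
    }
    nzp = p[p > 0]
    hxy = float(-np.sum(nzp * np.log2(nzp)))
    out["joint_entropy"] = hxy
    if var_i > 0 and var_j > 0:
        out["correlation"] = float(
            np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j)
        )
    else:
        out["correlation"] = np.nan
    # second measure of information correlation
    outer = pi[:, None] * pi[None, :]
    nz = outer > 0
    hxy2 = float(-np.sum(outer[nz] * np.log2(outer[nz])))
    out["information_correlation_2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    return out


def _run_or_zone_features(counts: np.ndarray, n_voxels: int,
                          small_name: str, large_name: str) -> dict[str, float]:
    """Shared emphasis/non-uniformity machinery for GLRLM-like matrices.

    ``counts`` is grey level x (run length | zone size | distance | dependence
    count); features are named generically and renamed by the caller.
    """
    ns = counts.sum()
    if ns == 0:
        return {}
    p = counts / ns
    G, J = counts.shape
    i = np.arange(1, G + 1)[:, None]
    j = np.arange(1, J + 1)[None, :]
    mu_j = float(np.sum(j * p))
    out = {
        small_name: float(np.sum(p / j ** 2)),
        large_name: float(np.sum(p * j ** 2)),
        "low_grey_level_emphasis": float(np.sum(p / i ** 2)),
        "high_grey_level_emphasis": float(np.sum(p * i ** 2)),
        f"{small_name}_low_grey": float(np.sum(p / (i ** 2 * j ** 2))),
        f"{small_name}_high_grey": float(np.sum(p * i ** 2 / j ** 2)),
        f"{large_name}_low_grey": float(np.sum(p * j ** 2 / i ** 2)),
        f"{large_name}_high_grey": float(np.sum(p * (i * j) ** 2)),
        "grey_level_nonuniformity": float(np.sum(counts.sum(axis=1) ** 2) / ns),
        "size_nonuniformity": float(np.sum(counts.sum(axis=0) ** 2) / ns),
        "size_variance": float(np.sum(p * (j - mu_j) ** 2)),
        "size_entropy_energy": float(np.sum(p ** 2)),
        "percentage": float(ns / n_voxels),
    }
    mu_i = float(np.sum(i * p))
    out["grey_level_variance"] = float(np.sum(p * (i - mu_i) ** 2))
    return out


_GLRLM_RENAME = {
    "short_run_emphasis": "short_run_emphasis",
    "long_run_emphasis": "long_run_emphasis",
    "short_run_emphasis_low_grey": "short_run_low_grey_level_emphasis",
    "short_run_emphasis_high_grey": "short_run_high_grey_level_emphasis",
    "long_run_emphasis_low_grey": "long_run_low_grey_level_emphasis",
    "long_run_emphasis_high_grey": "long_run_high_grey_level_emphasis",
    "size_nonuniformity": "run_length_nonuniformity",
    "size_variance": "run_length_variance",
    "percentage": "run_percentage",
}

_GLSZM_RENAME = {
    "small_zone_emphasis": "small_zone_emphasis",
    "large_zone_emphasis": "large_zone_emphasis",
    "small_zone_emphasis_low_grey": "small_zone_low_grey_level_emphasis",
    "small_zone_emphasis_high_grey": "small_zone_high_grey_level_emphasis",
    "large_zone_emphasis_low_grey": "large_zone_low_grey_level_emphasis",
    "large_zone_emphasis_high_grey": "large_zone_high_grey_level_emphasis",
    "size_nonuniformity": "zone_size_nonuniformity",
    "size_variance": "zone_size_variance",
    "percentage": "zone_percentage",
}

_GLDZM_RENAME = {
    "small_distance_emphasis": "small_distance_emphasis",
    "large_distance_emphasis": "large_distance_emphasis",
    "small_distance_emphasis_low_grey": "small_distance_low_grey_level_emphasis",
    "small_distance_emphasis_high_grey": "small_distance_high_grey_level_emphasis",
    "large_distance_emphasis_low_grey": "large_distance_low_grey_level_emphasis",
    "large_distance_emphasis_high_grey": "large_distance_high_grey_level_emphasis",
    "size_nonuniformity": "zone_distance_nonuniformity",
    "size_variance": "zone_distance_variance",
}

_NGLDM_RENAME = {
    "low_dependence_emphasis": "low_dependence_emphasis",
    "high_dependence_emphasis": "high_dependence_emphasis",
    "low_dependence_emphasis_low_grey": "low_dependence_low_grey_level_emphasis",
    "low_dependence_emphasis_high_grey": "low_dependence_high_grey_level_emphasis",
    "high_dependence_emphasis_low_grey": "high_dependence_low_grey_level_emphasis",
    "high_dependence_emphasis_high_grey": "high_dependence_high_grey_level_emphasis",
    "size_nonuniformity": "dependence_count_nonuniformity",
    "size_variance": "dependence_count_variance",
    "size_entropy_energy": "dependence_count_energy",
}


def _rename(raw: dict[str, float], small: str, large: str,
            table: dict[str, str], keep_low_high: bool = True) -> dict[str, float]:
    out = {}
    for k, v in raw.items():
        name = table.get(k, k)
        if name in ("size_entropy_energy",) :
            continue
        out[name] = v
    if not keep_low_high:
        out.pop("low_grey_level_emphasis", None)
        out.pop("high_grey_level_emphasis", None)
    return out


def _ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    nv = n.sum()
    if nv == 0:
        return {}
    p = n / nv
    G = n.size
    levels = np.arange(1, G + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ps = float(np.sum(p * s))
    out: dict[str, float] = {}
    out["coarseness"] = float(1.0 / ps) if ps > 0 else np.nan
    if ngp > 1:
        ii = levels[present][:, None]
        jj = levels[present][None, :]
        pp_i = p[present][:, None]
        pp_j = p[present][None, :]
        ss_i = s[present][:, None]
        ss_j = s[present][None, :]
        out["contrast"] = float(
            np.sum(pp_i * pp_j * (ii - jj) ** 2) / (ngp * (ngp - 1)) * (s.sum() / nv)
        )
        denom = np.sum(np.abs(ii * pp_i - jj * pp_j))
        out["busyness"] = float(ps / denom) if denom > 0 else np.nan
        out["complexity"] = float(
            np.sum(np.abs(ii - jj) * (pp_i * ss_i + pp_j * ss_j) / (pp_i + pp_j)) / nv
        )
        ssum = s.sum()
        out["strength"] = (
            float(np.sum((pp_i + pp_j) * (ii - jj) ** 2) / ssum) if ssum > 0 else np.nan
        )
    else:
        out["contrast"] = np.nan
        out["busyness"] = np.nan
        out["complexity"] = np.nan
        out["strength"] = np.nan
    return out


def _average_directions(per_dir: list[dict[str, float]]) -> dict[str, float]:
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


def texture_features(matrices: TextureMatrices) -> dict[str, float]:
    """All texture features, keyed ``family/feature``."""
    out: dict[str, float] = {}

    glcm_dir = [_glcm_features(m) for m in matrices.glcm]
    for k, v in _average_directions(glcm_dir).items():
        out[f"glcm/{k}"] = v

    glrlm_dir = [
        _rename(
            _run_or_zone_features(m, matrices.n_voxels, "short_run_emphasis",
                                  "long_run_emphasis"),
            "short_run_emphasis", "long_run_emphasis", _GLRLM_RENAME,
        )
        for m in matrices.glrlm
    ]
    for k, v in _average_directions(glrlm_dir).items():
        out[f"glrlm/{k}"] = v

    for k, v in _rename(
        _run_or_zone_features(matrices.glszm, matrices.n_voxels,
                              "small_zone_emphasis", "large_zone_emphasis"),
        "small_zone_emphasis", "large_zone_emphasis", _GLSZM_RENAME,
    ).items():
        out[f"glszm/{k}"] = v

    gldzm_raw = _rename(
        _run_or_zone_features(matrices.gldzm, matrices.n_voxels,
                              "small_distance_emphasis", "large_distance_emphasis"),
        "small_distance_emphasis", "large_distance_emphasis", _GLDZM_RENAME,
    )
    gldzm_raw.pop("percentage", None)
    for k, v in gldzm_raw.items():
        out[f"gldzm/{k}"] = v

    for k, v in _ngtdm_features(matrices.ngtdm_n, matrices.ngtdm_s).items():
        out[f"ngtdm/{k}"] = v

    ngldm_raw = _rename(
        _run_or_zone_features(matrices.ngldm, matrices.n_voxels,
                              "low_dependence_emphasis", "high_dependence_emphasis"),
        "low_dependence_emphasis", "high_dependence_emphasis", _NGLDM_RENAME,
    )
    ngldm_raw.pop("percentage", None)
    ngldm_raw["dependence_count_energy"] = float(
        np.sum((matrices.ngldm / matrices.ngldm.sum()) ** 2)
    )
    # rename the low/high grey marginals to the NGLDM "count" vocabulary
    ngldm_raw["low_grey_level_count_emphasis"] = ngldm_raw.pop("low_grey_level_emphasis")
    ngldm_raw["high_grey_level_count_emphasis"] = ngldm_raw.pop("high_grey_level_emphasis")
    for k, v in ngldm_raw.items():
        out[f"ngldm/{k}"] = v

    return out
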
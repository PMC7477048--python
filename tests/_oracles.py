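"""Independent brute-force implementations used as oracles in tests.

Everything here is written as plain loops straight from the textbook
definitions, deliberately sharing no code with the package: matrices are
assembled pair by pair, features are summed term by term.  Slow but
transparent; intended for tiny grids only.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np

NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


# ------------------------------------------------------------ first order

def naive_first_order(values, mask, spacing_mm):
    vals = []
    for idx in np.ndindex(mask.shape):
        if mask[idx]:
            vals.append(values[idx])
    n = len(vals)
    vvol = spacing_mm[0] * spacing_mm[1] * spacing_mm[2] / 1000.0
    mean = sum(vals) / n
    return {
        "suv_max": max(vals),
        "suv_mean": mean,
        "matv_ml": n * vvol,
        "tlg": mean * n * vvol,
    }


def naive_suvpeak(values, mask, spacing_mm, volume_ml=1.0):
    """Max over region voxels of the mean SUV in a sphere, by enumeration."""
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    shape = values.shape
    best = -math.inf
    centers = [idx for idx in np.ndindex(shape) if mask[idx]]
    for c in centers:
        member_vals = []
        for idx in np.ndindex(shape):
            d2 = sum(((a - b) * s) ** 2 for a, b, s in zip(idx, c, spacing_mm))
            if d2 <= radius ** 2 + 1e-9:
                member_vals.append(values[idx])
        best = max(best, sum(member_vals) / len(member_vals))
    return best


# ------------------------------------------------------------ intensity

def naive_intensity(values, mask, levels, n_levels):
    x = [values[idx] for idx in np.ndindex(mask.shape) if mask[idx]]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    out = {
        "stat/mean": mean,
        "stat/variance": var,
        "stat/range": max(x) - min(x),
        "stat/energy": sum(v ** 2 for v in x),
        "stat/root_mean_square": math.sqrt(sum(v ** 2 for v in x) / n),
        "stat/coefficient_of_variation": sd / mean if mean != 0 else float("nan"),
        "stat/skewness": (sum(((v - mean) / sd) ** 3 for v in x) / n
                          if sd > 0 else float("nan")),
        "stat/kurtosis": (sum(((v - mean) / sd) ** 4 for v in x) / n - 3.0
                          if sd > 0 else float("nan")),
    }
    lev = [levels[idx] for idx in np.ndindex(mask.shape) if mask[idx]]
    counts = [lev.count(g) for g in range(1, n_levels + 1)]
    probs = [c / n for c in counts]
    out["ih/entropy"] = -sum(p * math.log2(p) for p in probs if p > 0)
    out["ih/uniformity"] = sum(p ** 2 for p in probs)
    lmean = sum(lev) / n
    lvar = sum((v - lmean) ** 2 for v in lev) / n
    out["ih/mean"] = lmean
    out["ih/variance"] = lvar
    out["ih/coefficient_of_variation"] = (
        math.sqrt(lvar) / lmean if lmean != 0 else float("nan")
    )
    if n_levels >= 2:
        grads = [counts[g + 1] - counts[g] for g in range(n_levels - 1)]
        out["ih/max_histogram_gradient"] = max(grads)
        out["ih/min_histogram_gradient"] = min(grads)
    lo, hi = min(x), max(x)
    def vfrac(f):
        if hi == lo:
            return 1.0
        thr = lo + f * (hi - lo)
        return sum(1 for v in x if v >= thr) / n
    out["ivh/v10"] = vfrac(0.10)
    out["ivh/v90"] = vfrac(0.90)
    out["ivh/volume_fraction_diff"] = vfrac(0.10) - vfrac(0.90)
    return out


def naive_morans_i(values, mask, spacing_mm):
    pts = [(idx, values[idx]) for idx in np.ndindex(mask.shape) if mask[idx]]
    n = len(pts)
    mean = sum(v for _, v in pts) / n
    num = 0.0
    wsum = 0.0
    for (ci, vi), (cj, vj) in product(pts, pts):
        if ci == cj:
            continue
        d = math.sqrt(sum(((a - b) * s) ** 2 for a, b, s in zip(ci, cj, spacing_mm)))
        w = 1.0 / d
        wsum += w
        num += w * (vi - mean) * (vj - mean)
    den = sum((v - mean) ** 2 for _, v in pts)
    return (n / wsum) * (num / den)


# ------------------------------------------------------------ matrices

def _in_grid(idx, shape):
    return all(0 <= a < s for a, s in zip(idx, shape))


def naive_glcm(levels, direction, G):
    """Symmetric co-occurrence counts for one direction."""
    m = np.zeros((G, G))
    shape = levels.shape
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        nb = tuple(a + d for a, d in zip(idx, direction))
        if _in_grid(nb, shape) and levels[nb] > 0:
            m[levels[idx] - 1, levels[nb] - 1] += 1
            m[levels[nb] - 1, levels[idx] - 1] += 1
    return m


def naive_glrlm(levels, direction, G):
    shape = levels.shape
    maxlen = max(shape)
    m = np.zeros((G, maxlen))
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        prev = tuple(a - d for a, d in zip(idx, direction))
        if _in_grid(prev, shape) and levels[prev] == g:
            continue  # not a run start
        length = 1
        nxt = tuple(a + d for a, d in zip(idx, direction))
        while _in_grid(nxt, shape) and levels[nxt] == g:
            length += 1
            nxt = tuple(a + d for a, d in zip(nxt, direction))
        m[g - 1, length - 1] += 1
    return m


def _flood_zones(levels, G):
    """26-connected equal-level zones; yields (level, set of voxels)."""
    shape = levels.shape
    seen = set()
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0 or idx in seen:
            continue
        stack = [idx]
        zone = set()
        while stack:
            cur = stack.pop()
            if cur in zone:
                continue
            zone.add(cur)
            for d in NEIGHBORS_26:
                nb = tuple(a + b for a, b in zip(cur, d))
                if _in_grid(nb, shape) and levels[nb] == g and nb not in zone:
                    stack.append(nb)
        seen |= zone
        yield g, zone


def naive_glszm(levels, G):
    n_vox = int((levels > 0).sum())
    m = np.zeros((G, n_vox))
    for g, zone in _flood_zones(levels, G):
        m[g - 1, len(zone) - 1] += 1
    w = 1
    for j in range(n_vox):
        if m[:, j].any():
            w = j + 1
    return m[:, :w]


def _chebyshev_edge_distance(levels, idx):
    """Chebyshev distance to the nearest non-mask voxel (grid border counts
    as outside); a voxel touching the edge has distance 1."""
    shape = levels.shape
    best = math.inf
    # distance to grid border
    for a, s in zip(idx, shape):
        best = min(best, a + 1, s - a)
    # distance to any non-mask voxel
    for other in np.ndindex(shape):
        if levels[other] == 0:
            d = max(abs(a - b) for a, b in zip(idx, other))
            best = min(best, d)
    return int(best)


def naive_gldzm(levels, G):
    dists = {
        idx: _chebyshev_edge_distance(levels, idx)
        for idx in np.ndindex(levels.shape)
        if levels[idx] > 0
    }
    max_d = max(dists.values())
    m = np.zeros((G, max_d))
    for g, zone in _flood_zones(levels, G):
        dz = min(dists[v] for v in zone)
        m[g - 1, dz - 1] += 1
    return m


def naive_ngtdm(levels, G):
    shape = levels.shape
    n = np.zeros(G)
    s = np.zeros(G)
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        nbrs = []
        for d in NEIGHBORS_26:
            nb = tuple(a + b for a, b in zip(idx, d))
            if _in_grid(nb, shape) and levels[nb] > 0:
                nbrs.append(levels[nb])
        if not nbrs:
            continue
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    return n, s


def naive_ngldm(levels, G, alpha=0):
    shape = levels.shape
    m = np.zeros((G, 27))
    for idx in np.ndindex(shape):
        g = levels[idx]
        if g == 0:
            continue
        dep = 1  # centre voxel included
        for d in NEIGHBORS_26:
            nb = tuple(a + b for a, b in zip(idx, d))
            if _in_grid(nb, shape) and levels[nb] > 0 and abs(levels[nb] - g) <= alpha:
                dep += 1
        m[g - 1, dep - 1] += 1
    return m


# ------------------------------------------------------------ features

def naive_glcm_features(m):
    total = m.sum()
    p = m / total
    G = m.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(G) for j in range(G))
    mu_j = sum((j + 1) * p[i, j] for i in range(G) for j in range(G))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(G) for j in range(G))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(G) for j in range(G))
    out = {}
    out["contrast"] = sum(p[i, j] * (i - j) ** 2 for i in range(G) for j in range(G))
    out["dissimilarity"] = sum(p[i, j] * abs(i - j) for i in range(G) for j in range(G))
    out["cluster_shade"] = sum(
        p[i, j] * (i + j + 2 - mu_i - mu_j) ** 3 for i in range(G) for j in range(G)
    )
    out["cluster_prominence"] = sum(
        p[i, j] * (i + j + 2 - mu_i - mu_j) ** 4 for i in range(G) for j in range(G)
    )
    out["energy"] = sum(p[i, j] ** 2 for i in range(G) for j in range(G))
    out["inverse_difference"] = sum(
        p[i, j] / (1 + abs(i - j)) for i in range(G) for j in range(G)
    )
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G)
    )
    hxy = -sum(
        p[i, j] * math.log2(p[i, j])
        for i in range(G) for j in range(G) if p[i, j] > 0
    )
    out["joint_entropy"] = hxy
    if var_i > 0 and var_j > 0:
        out["correlation"] = sum(
            (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j]
            for i in range(G) for j in range(G)
        ) / math.sqrt(var_i * var_j)
    else:
        out["correlation"] = float("nan")
    pi = [sum(p[i, j] for j in range(G)) for i in range(G)]
    hxy2 = -sum(
        pi[i] * pi[j] * math.log2(pi[i] * pi[j])
        for i in range(G) for j in range(G) if pi[i] * pi[j] > 0
    )
    out["information_correlation_2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
    )
    return out


def _naive_rz(m, n_voxels):
    """Generic emphasis features for level x size matrices (index base 1)."""
    ns = m.sum()
    G, J = m.shape
    p = m / ns
    out = {}
    out["small"] = sum(p[i, j] / (j + 1) ** 2 for i in range(G) for j in range(J))
    out["large"] = sum(p[i, j] * (j + 1) ** 2 for i in range(G) for j in range(J))
    out["lgle"] = sum(p[i, j] / (i + 1) ** 2 for i in range(G) for j in range(J))
    out["hgle"] = sum(p[i, j] * (i + 1) ** 2 for i in range(G) for j in range(J))
    out["small_low"] = sum(
        p[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(G) for j in range(J)
    )
    out["small_high"] = sum(
        p[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(G) for j in range(J)
    )
    out["large_low"] = sum(
        p[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(G) for j in range(J)
    )
    out["large_high"] = sum(
        p[i, j] * ((i + 1) * (j + 1)) ** 2 for i in range(G) for j in range(J)
    )
    out["gln"] = sum(sum(m[i, :]) ** 2 for i in range(G)) / ns
    out["szn"] = sum(sum(m[:, j]) ** 2 for j in range(J)) / ns
    mu = sum((j + 1) * p[i, j] for i in range(G) for j in range(J))
    out["size_var"] = sum(
        p[i, j] * (j + 1 - mu) ** 2 for i in range(G) for j in range(J)
    )
    mu_g = sum((i + 1) * p[i, j] for i in range(G) for j in range(J))
    out["grey_var"] = sum(
        p[i, j] * (i + 1 - mu_g) ** 2 for i in range(G) for j in range(J)
    )
    out["pct"] = ns / n_voxels
    out["energy"] = sum(p[i, j] ** 2 for i in range(G) for j in range(J))
    return out


def naive_glrlm_features(m, n_voxels):
    r = _naive_rz(m, n_voxels)
    return {
        "short_run_emphasis": r["small"],
        "long_run_emphasis": r["large"],
        "low_grey_level_emphasis": r["lgle"],
        "high_grey_level_emphasis": r["hgle"],
        "short_run_low_grey_level_emphasis": r["small_low"],
        "short_run_high_grey_level_emphasis": r["small_high"],
        "long_run_low_grey_level_emphasis": r["large_low"],
        "long_run_high_grey_level_emphasis": r["large_high"],
        "grey_level_nonuniformity": r["gln"],
        "run_length_nonuniformity": r["szn"],
        "run_length_variance": r["size_var"],
        "grey_level_variance": r["grey_var"],
        "run_percentage": r["pct"],
    }


def naive_glszm_features(m, n_voxels):
    r = _naive_rz(m, n_voxels)
    return {
        "small_zone_emphasis": r["small"],
        "large_zone_emphasis": r["large"],
        "low_grey_level_emphasis": r["lgle"],
        "high_grey_level_emphasis": r["hgle"],
        "small_zone_low_grey_level_emphasis": r["small_low"],
        "small_zone_high_grey_level_emphasis": r["small_high"],
        "large_zone_low_grey_level_emphasis": r["large_low"],
        "large_zone_high_grey_level_emphasis": r["large_high"],
        "grey_level_nonuniformity": r["gln"],
        "zone_size_nonuniformity": r["szn"],
        "zone_size_variance": r["size_var"],
        "grey_level_variance": r["grey_var"],
        "zone_percentage": r["pct"],
    }


def naive_gldzm_features(m, n_voxels):
    r = _naive_rz(m, n_voxels)
    return {
        "small_distance_emphasis": r["small"],
        "large_distance_emphasis": r["large"],
        "low_grey_level_emphasis": r["lgle"],
        "high_grey_level_emphasis": r["hgle"],
        "small_distance_low_grey_level_emphasis": r["small_low"],
        "small_distance_high_grey_level_emphasis": r["small_high"],
        "large_distance_low_grey_level_emphasis": r["large_low"],
        "large_distance_high_grey_level_emphasis": r["large_high"],
        "grey_level_nonuniformity": r["gln"],
        "zone_distance_nonuniformity": r["szn"],
        "zone_distance_variance": r["size_var"],
        "grey_level_variance": r["grey_var"],
    }


def naive_ngldm_features(m, n_voxels):
    r = _naive_rz(m, n_voxels)
    return {
        "low_dependence_emphasis": r["small"],
        "high_dependence_emphasis": r["large"],
        "low_grey_level_count_emphasis": r["lgle"],
        "high_grey_level_count_emphasis": r["hgle"],
        "low_dependence_low_grey_level_emphasis": r["small_low"],
        "low_dependence_high_grey_level_emphasis": r["small_high"],
        "high_dependence_low_grey_level_emphasis": r["large_low"],
        "high_dependence_high_grey_level_emphasis": r["large_high"],
        "grey_level_nonuniformity": r["gln"],
        "dependence_count_nonuniformity": r["szn"],
        "dependence_count_variance": r["size_var"],
        "grey_level_variance": r["grey_var"],
        "dependence_count_energy": r["energy"],
    }


def naive_ngtdm_features(n, s):
    nv = n.sum()
    G = len(n)
    p = [v / nv for v in n]
    present = [i for i in range(G) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in range(G))
    out = {}
    out["coarseness"] = 1.0 / ps if ps > 0 else float("nan")
    if ngp > 1:
        out["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum(s) / nv)
        denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        out["busyness"] = ps / denom if denom > 0 else float("nan")
        out["complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / nv
        ssum = sum(s)
        out["strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
            if ssum > 0 else float("nan")
        )
    else:
        out.update({"contrast": float("nan"), "busyness": float("nan"),
                    "complexity": float("nan"), "strength": float("nan")})
    return out


def naive_all_texture(levels, G):
    """Full texture feature dict keyed family/name, matching the package."""
    n_vox = int((levels > 0).sum())
    out = {}
    per_dir = [naive_glcm_features(naive_glcm(levels, d, G)) for d in DIRECTIONS_13]
    for key in per_dir[0]:
        out[f"glcm/{key}"] = float(np.mean([d[key] for d in per_dir]))
    per_dir = [
        naive_glrlm_features(naive_glrlm(levels, d, G), n_vox) for d in DIRECTIONS_13
    ]
    for key in per_dir[0]:
        out[f"glrlm/{key}"] = float(np.mean([d[key] for d in per_dir]))
    for key, v in naive_glszm_features(naive_glszm(levels, G), n_vox).items():
        out[f"glszm/{key}"] = v
    for key, v in naive_gldzm_features(naive_gldzm(levels, G), n_vox).items():
        out[f"gldzm/{key}"] = v
    n, s = naive_ngtdm(levels, G)
    for key, v in naive_ngtdm_features(n, s).items():
        out[f"ngtdm/{key}"] = v
    for key, v in naive_ngldm_features(naive_ngldm(levels, G), n_vox).items():
        out[f"ngldm/{key}"] = v
    return out


# ------------------------------------------------------------ graph cover

def exhaustive_min_vertex_cover(nodes, edges):
    """Smallest vertex cover by subset enumeration (tiny graphs only)."""
    nodes = list(nodes)
    for size in range(len(nodes) + 1):
        for subset in combinations(nodes, size):
            ss = set(subset)
            if all(u in ss or v in ss for u, v in edges):
                return ss
    raise AssertionError("unreachable")


def naive_morphology_axes(mask, spacing_mm):
    """Axis lengths from the coordinate covariance, summed explicitly."""
    coords = [
        [a * s for a, s in zip(idx, spacing_mm)]
        for idx in np.ndindex(mask.shape)
        if mask[idx]
    ]
    n = len(coords)
    means = [sum(c[a] for c in coords) / n for a in range(3)]
    cov = [[0.0] * 3 for _ in range(3)]
    for c in coords:
        for a in range(3):
            for b in range(3):
                cov[a][b] += (c[a] - means[a]) * (c[b] - means[b]) / n
    eig = sorted(np.linalg.eigvalsh(np.array(cov)), reverse=True)
    eig = [max(e, 0.0) for e in eig]
    out = {
        "morph/major_axis_length_mm": 4.0 * math.sqrt(eig[0]),
        "morph/minor_axis_length_mm": 4.0 * math.sqrt(eig[1]),
        "morph/least_axis_length_mm": 4.0 * math.sqrt(eig[2]),
        "morph/volume_voxel_ml": n * spacing_mm[0] * spacing_mm[1] * spacing_mm[2] / 1000.0,
    }
    if eig[0] > 0:
        out["morph/elongation"] = math.sqrt(eig[1] / eig[0])
        out["morph/flatness"] = math.sqrt(eig[2] / eig[0])
    else:
        out["morph/elongation"] = float("nan")
        out["morph/flatness"] = float("nan")
    return out
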
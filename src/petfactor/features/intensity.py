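"""First-order intensity, intensity-histogram and intensity-volume-histogram
features.

Histogram features operate on the fixed-bin-size discretized grey levels;
histogram gradients are the first differences of the grey-level counts,
so a histogram with counts (2, 5, 3) over consecutive levels has gradients
(+3, -2).  Intensity-volume-histogram (IVH) features relate the fraction of
the lesion volume above an intensity to the intensity fraction; the
``volume_fraction_diff`` feature is V10 - V90, the volume-fraction
difference between the 10% and 90% intensity fractions.
"""

from __future__ import annotations

import numpy as np

from ..volume import LesionMask, PETVolume
from .discretize import DiscretizedVolume


def _ivh_volume_fraction(suv: np.ndarray, intensity_fraction: float) -> float:
    """Fraction of voxels with intensity above the given intensity fraction
    of the lesion's [min, max] range."""
    lo, hi = suv.min(), suv.max()
    if hi == lo:
        return 1.0
    thr = lo + intensity_fraction * (hi - lo)
    return float(np.mean(suv >= thr))


def intensity_features(volume: PETVolume, mask: LesionMask,
                       discretized: DiscretizedVolume) -> dict[str, float]:
    """Intensity features keyed ``stat/``, ``ih/`` and ``ivh/``."""
    x = volume.values[mask.support].astype(float)
    n = x.size
    if n == 0:
        raise ValueError("mask is empty")
    mu = x.mean()
    var = x.var()  # population variance, 1/n
    sd = np.sqrt(var)
    out: dict[str, float] = {
        "stat/mean": float(mu),
        "stat/variance": float(var),
        "stat/range": float(x.max() - x.min()),
        "stat/energy": float(np.sum(x ** 2)),
        "stat/root_mean_square": float(np.sqrt(np.mean(x ** 2))),
        "stat/coefficient_of_variation": float(sd / mu) if mu != 0 else np.nan,
    }
    if sd > 0:
        z = (x - mu) / sd
        out["stat/skewness"] = float(np.mean(z ** 3))
        out["stat/kurtosis"] = float(np.mean(z ** 4) - 3.0)
    else:
        out["stat/skewness"] = np.nan
        out["stat/kurtosis"] = np.nan

    # intensity-histogram features on discretized levels
    lev = discretized.levels_in_mask()
    G = discretized.n_levels
    counts = np.bincount(lev, minlength=G + 1)[1:].astype(float)
    p = counts / counts.sum()
    nz = p > 0
    out["ih/entropy"] = float(-np.sum(p[nz] * np.log2(p[nz])))
    out["ih/uniformity"] = float(np.sum(p ** 2))
    lev_mu = lev.mean()
    lev_sd = lev.std()
    out["ih/mean"] = float(lev_mu)
    out["ih/variance"] = float(lev.var())
    out["ih/coefficient_of_variation"] = float(lev_sd / lev_mu) if lev_mu != 0 else np.nan
    if G >= 2:
        grad = np.diff(counts)
        out["ih/max_histogram_gradient"] = float(grad.max())
        out["ih/min_histogram_gradient"] = float(grad.min())
        out["ih/max_histogram_gradient_level"] = float(np.argmax(grad) + 1)
        out["ih/min_histogram_gradient_level"] = float(np.argmin(grad) + 1)
    else:
        out["ih/max_histogram_gradient"] = np.nan
        out["ih/min_histogram_gradient"] = np.nan
        out["ih/max_histogram_gradient_level"] = np.nan
        out["ih/min_histogram_gradient_level"] = np.nan

    v10 = _ivh_volume_fraction(x, 0.10)
    v90 = _ivh_volume_fraction(x, 0.90)
    out["ivh/v10"] = v10
    out["ivh/v90"] = v90
    out["ivh/volume_fraction_diff"] = v10 - v90
    return out
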
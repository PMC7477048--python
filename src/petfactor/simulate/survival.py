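"""Proportional-hazards survival outcomes with right censoring.

Event times follow hazard(t | x) = h0(t) * exp(x' beta) with an exponential
(constant h0) or Weibull baseline.  Censoring combines an independent
exponential censoring process (tuned to the requested censoring fraction)
and an administrative cutoff at the follow-up horizon (24 months by
default, matching a 2-year outcome window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SurvivalGroundTruth:
    true_beta: np.ndarray
    baseline_hazard_rate: float = 0.03     # events per month
    censoring_rate: float = 0.2            # pre-horizon random censoring fraction
    horizon_months: float = 24.0
    weibull_shape: float = 1.0             # 1 = exponential baseline
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_beta = np.atleast_1d(np.asarray(self.true_beta, float))
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.horizon_months <= 0 or self.baseline_hazard_rate <= 0:
            raise ValueError("horizon and baseline hazard must be positive")


def generate_survival(X, gt: SurvivalGroundTruth) -> pd.DataFrame:
    """Event table (time_months, event) for predictor matrix ``X`` (n x p)."""
    X = np.atleast_2d(np.asarray(X, float))
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")
    if X.shape[1] != gt.true_beta.size:
        raise ValueError("predictor count does not match true_beta")
    rng = np.random.default_rng(gt.seed)
    n = X.shape[0]
    lp = X @ gt.true_beta
    u = rng.uniform(size=n)
    # inverse transform for Weibull baseline H0(t) = h0 * t^shape
    h = gt.baseline_hazard_rate * np.exp(lp)
    t_event = (-np.log(u) / h) ** (1.0 / gt.weibull_shape)
    if gt.censoring_rate > 0:
        # exponential censoring with mean matched to the baseline time scale
        c_rate = gt.baseline_hazard_rate * gt.censoring_rate / (1 - gt.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_admin = gt.horizon_months
    time = np.minimum.reduce([t_event, t_cens, np.full(n, t_admin)])
    event = (t_event <= t_cens) & (t_event <= t_admin)
    time = np.maximum(time, 1e-6)  # strictly positive follow-up
    return pd.DataFrame({"time_months": time, "event": event.astype(int)})
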
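"""Two-year risk calculator and three-tier risk stratification.

From a fitted Cox model the absolute risk of the event by the horizon
(24 months) is

    risk(x) = 1 - exp(-H0(24))^exp(lp(x)),   lp(x) = sum_j beta_j (x_j - mean_j)

with H0 the Breslow baseline cumulative hazard of a training-mean patient.
Patients are stratified into low (< 33%), medium (33-66%) and high
(>= 66%) absolute risk; a quantile (tertile) mode is available as an
alternative convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .prognostics import CoxFit, logrank

STRATUM_CUTS = (0.33, 0.66)
DEFAULT_HORIZON = 24.0


def baseline_cumhaz_at(fit: CoxFit, horizon: float = DEFAULT_HORIZON) -> float:
    """Breslow baseline cumulative hazard evaluated at the horizon
    (step function: last value at or before the horizon)."""
    ch = fit.baseline_cumhaz.iloc[:, 0]
    eligible = ch[ch.index <= horizon]
    return float(eligible.iloc[-1]) if len(eligible) else 0.0


def risk_2yr(fit: CoxFit, covariates: pd.DataFrame,
             horizon: float = DEFAULT_HORIZON) -> pd.DataFrame:
    """Per-patient linear predictor, absolute risk by the horizon, stratum."""
    lp = fit.linear_predictor(covariates) if fit.predictors else np.zeros(len(covariates))
    h0 = baseline_cumhaz_at(fit, horizon)
    risk = 1.0 - np.exp(-h0 * np.exp(lp))
    return pd.DataFrame(
        {
            "linear_predictor": lp,
            "risk_2yr": risk,
            "stratum": stratify(risk),
        },
        index=covariates.index,
    )


def stratify(risk, cuts: tuple[float, float] = STRATUM_CUTS,
             mode: str = "threshold") -> np.ndarray:
    """Assign low/medium/high strata.

    ``threshold`` mode applies the cuts to absolute risk (boundary
    convention: risk = 0.33 is medium, risk = 0.66 is high); ``quantile``
    mode uses cohort tertiles of the risk distribution instead.
    """
    r = np.atleast_1d(np.asarray(risk, float))
    if np.any((r < 0) | (r > 1)):
        raise ValueError("risks must lie in [0, 1]")
    if mode == "quantile":
        lo, hi = np.quantile(r, [1 / 3, 2 / 3])
    elif mode == "threshold":
        lo, hi = cuts
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    out = np.where(r >= hi, "high", np.where(r >= lo, "medium", "low"))
    return out


def evaluate_strata(strata: np.ndarray, time, event,
                    horizon: float = DEFAULT_HORIZON):
    """Kaplan-Meier curves per stratum plus the overall log-rank test.

    Returns (km_fits, chi2, p, survival_at_horizon) where the last item maps
    stratum -> KM survival at the horizon.  Empty strata are dropped with a
    warning from the caller's perspective (they simply do not appear).
    """
    strata = np.asarray(strata)
    present = [s for s in ("low", "medium", "high") if (strata == s).any()]
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty strata")
    km_fits: dict[str, KaplanMeierFitter] = {}
    surv_at: dict[str, float] = {}
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    for s in present:
        sel = strata == s
        km = KaplanMeierFitter().fit(t[sel], e[sel], label=s)
        km_fits[s] = km
        surv_at[s] = float(km.survival_function_at_times(horizon).iloc[0])
    keep = np.isin(strata, present)
    chi2, p = logrank(t[keep], e[keep], strata[keep])
    return km_fits, chi2, p, surv_at


def export_calculator(fit: CoxFit, horizon: float = DEFAULT_HORIZON) -> pd.DataFrame:
    """Human-readable calculator table.

    One row per predictor (coefficient and training mean) plus a baseline
    row holding the survival of a training-mean patient at the horizon.
    Filling in a patient's covariates and applying

        risk = 1 - S0 ^ exp(sum_j beta_j (x_j - mean_j))

    reproduces :func:`risk_2yr` exactly.  Binary covariates keep their
    model coding (e.g. HPV status: 0 = negative, 1 = positive).
    """
    h0 = baseline_cumhaz_at(fit, horizon)
    rows = [
        {
            "term": name,
            "coefficient": float(fit.beta[name]),
            "training_mean": float(fit.training_means[name]),
        }
        for name in fit.predictors
    ]
    rows.append(
        {
            "term": f"baseline_survival_{int(horizon)}mo",
            "coefficient": np.nan,
            "training_mean": float(np.exp(-h0)),
        }
    )
    return pd.DataFrame(rows)


def calculator_risk(table: pd.DataFrame, patient: dict[str, float]) -> float:
    """Apply an exported calculator table to one patient's covariates."""
    base_row = table.iloc[-1]
    s0 = float(base_row["training_mean"])
    lp = 0.0
    for _, row in table.iloc[:-1].iterrows():
        name = row["term"]
        if name not in patient:
            raise ValueError(f"missing covariate {name!r}")
        lp += row["coefficient"] * (patient[name] - row["training_mean"])
    return float(1.0 - s0 ** np.exp(lp))
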
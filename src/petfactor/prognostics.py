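"""Survival modelling and validation statistics.

Cox proportional-hazards fits (Efron ties, Breslow baseline hazard) via
lifelines; multivariable models are reduced by backward elimination with the
TRIPOD-style retention rule p <= 0.157.  Validation uses Harrell's
concordance index with a pairwise U-statistic standard error, incident/
dynamic time-dependent ROC AUC with inverse-probability-of-censoring
weighting, stratified 5-fold cross-validation, and likelihood-ratio
comparison of nested models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

P_KEEP = 0.157  # TRIPOD-style retention threshold


# ---------------------------------------------------------------- screening

def spearman_screen(a: pd.DataFrame, b: pd.DataFrame, alpha: float = 0.05):
    """Spearman correlations of every column of ``a`` against every column
    of ``b`` with Bonferroni-corrected significance.

    Returns (r, p, significant) DataFrames indexed by a-columns x b-columns.
    Constant (all-ties) columns give NaN correlations.
    """
    n = len(a)
    if len(b) != n or n < 5:
        raise ValueError("need paired observations, n >= 5")
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    p = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            if a[ca].nunique() <= 1 or b[cb].nunique() <= 1:
                r.loc[ca, cb] = np.nan
                p.loc[ca, cb] = np.nan
                continue
            rho, pv = stats.spearmanr(a[ca], b[cb])
            r.loc[ca, cb] = rho
            p.loc[ca, cb] = pv
    n_tests = int(p.notna().sum().sum())
    threshold = alpha / max(n_tests, 1)
    significant = p < threshold
    return r, p, significant


def logrank(time: np.ndarray, event: np.ndarray, group: np.ndarray):
    """Log-rank test across >= 2 groups; returns (chi2 statistic, p)."""
    event = np.asarray(event)
    if np.unique(np.asarray(group)).size < 2:
        raise ValueError("need at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------- Cox fits

@dataclass
class CoxFit:
    predictors: list[str]
    beta: pd.Series
    se: pd.Series
    p: pd.Series
    baseline_cumhaz: pd.DataFrame      # Breslow baseline (covariates at training means)
    loglik: float
    training_means: pd.Series
    duration_col: str
    event_col: str
    fitter: CoxPHFitter | None = field(default=None, repr=False)
    elimination_path: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.predictors)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        """Centered linear predictor sum_j beta_j (x_j - mean_j,train)."""
        missing = [c for c in self.predictors if c not in data.columns]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        X = data[self.predictors].astype(float)
        return ((X - self.training_means[self.predictors]) @ self.beta).to_numpy()


def cox_fit(data: pd.DataFrame, duration_col: str, event_col: str,
            predictors: list[str]) -> CoxFit:
    """Cox partial-likelihood fit with Efron tie handling."""
    if not predictors:
        raise ValueError("no predictors given")
    for c in predictors:
        if data[c].nunique() <= 1:
            raise ValueError(f"constant predictor {c!r}")
    n_events = int(data[event_col].sum())
    if n_events < len(predictors):
        logger.warning("only %d events for %d predictors", n_events, len(predictors))
    cph = CoxPHFitter()
    cols = predictors + [duration_col, event_col]
    try:
        cph.fit(data[cols], duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    return CoxFit(
        predictors=list(predictors),
        beta=cph.params_.copy(),
        se=cph.standard_errors_.copy(),
        p=cph.summary["p"].copy(),
        baseline_cumhaz=cph.baseline_cumulative_hazard_.copy(),
        loglik=float(cph.log_likelihood_),
        training_means=data[predictors].astype(float).mean(),
        duration_col=duration_col,
        event_col=event_col,
        fitter=cph,
    )


def null_loglik(data: pd.DataFrame, duration_col: str, event_col: str) -> float:
    """Partial log-likelihood of the null (beta = 0) Cox model."""
    t = data[duration_col].to_numpy()
    e = data[event_col].to_numpy().astype(bool)
    ll = 0.0
    for time in np.unique(t[e]):
        d = int(np.sum((t == time) & e))
        at_risk = int(np.sum(t >= time))
        # with beta = 0 the Efron denominators are at_risk - r, r = 0..d-1
        for r in range(d):
            ll -= np.log(at_risk - r)
    return float(ll)


def backward_select(data: pd.DataFrame, duration_col: str, event_col: str,
                    candidates: list[str], p_keep: float = P_KEEP) -> CoxFit:
    """Backward elimination: drop the weakest predictor with p > p_keep,
    refit, repeat.  Returns a null-model sentinel if everything drops."""
    current = list(candidates)
    path: list[tuple[str, float]] = []
    while current:
        fit = cox_fit(data, duration_col, event_col, current)
        worst = fit.p.idxmax()
        if fit.p[worst] <= p_keep:
            fit.elimination_path = path
            return fit
        path.append((worst, float(fit.p[worst])))
        logger.info("dropping %r (p=%.3f > %.3f)", worst, fit.p[worst], p_keep)
        current.remove(worst)
    logger.warning("backward elimination removed every candidate; null model")
    km = KaplanMeierFitter().fit(data[duration_col], data[event_col])
    nll = null_loglik(data, duration_col, event_col)
    surv = np.clip(km.survival_function_["KM_estimate"].to_numpy(), 1e-12, None)
    cumhaz = pd.DataFrame(
        {"baseline cumulative hazard": -np.log(surv)},
        index=km.survival_function_.index,
    )
    null = CoxFit(
        predictors=[], beta=pd.Series(dtype=float), se=pd.Series(dtype=float),
        p=pd.Series(dtype=float), baseline_cumhaz=cumhaz, loglik=nll,
        training_means=pd.Series(dtype=float), duration_col=duration_col,
        event_col=event_col,
    )
    null.elimination_path = path
    return null


# ---------------------------------------------------------------- metrics

def harrell_c(time, event, risk_score) -> tuple[float, float]:
    """Harrell's concordance index and a pairwise U-statistic SE.

    Comparable pairs: the earlier subject experienced the event (pairs tied
    on time with two events are not comparable).  Tied risk scores count
    one half.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, bool)
    r = np.asarray(risk_score, float)
    n = t.size
    # pair masks: i is the earlier event
    earlier = (t[:, None] < t[None, :]) & e[:, None]
    tied_time = (t[:, None] == t[None, :]) & e[:, None] & ~e[None, :]
    comparable = earlier | tied_time
    if not comparable.any():
        raise ValueError("no comparable pairs")
    conc = np.where(r[:, None] > r[None, :], 1.0,
                    np.where(r[:, None] == r[None, :], 0.5, 0.0))
    num = float(np.sum(conc * comparable))
    den = float(np.sum(comparable))
    c = num / den
    # U-statistic SE from per-subject mean contributions
    pair_c = np.where(comparable, conc, 0.0)
    sym_count = comparable + comparable.T
    sym_c = pair_c + pair_c.T
    counts = sym_count.sum(axis=1)
    with np.errstate(invalid="ignore"):
        subj = np.where(counts > 0, sym_c.sum(axis=1) / np.maximum(counts, 1), np.nan)
    subj = subj[counts > 0]
    m = subj.size
    se = float(2.0 * np.std(subj, ddof=1) / np.sqrt(m)) if m > 1 else np.nan
    return c, se


def concordance(fit: CoxFit, data: pd.DataFrame) -> tuple[float, float]:
    """Concordance of a fitted model's risk score on a dataset."""
    lp = fit.linear_predictor(data)
    return harrell_c(data[fit.duration_col], data[fit.event_col], lp)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    km = KaplanMeierFitter()
    km.fit(time, 1 - np.asarray(event))
    return km


def incident_auc(fit: CoxFit, data: pd.DataFrame,
                 horizon: float = 24.0) -> tuple[pd.DataFrame, float]:
    """Incident/dynamic time-dependent ROC AUC.

    At each distinct event time t <= horizon, cases are the subjects failing
    at t and controls those still at risk after t; AUC(t) compares their
    risk scores.  The summary is the mean of AUC(t) weighted by
    (cases x controls) / G(t-)^2, with G the Kaplan-Meier censoring
    survival (IPCW).
    """
    t = data[fit.duration_col].to_numpy(float)
    e = data[fit.event_col].to_numpy(bool)
    r = fit.linear_predictor(data)
    event_times = np.unique(t[e & (t <= horizon)])
    if event_times.size == 0:
        raise ValueError("no events before the horizon")
    G = _censoring_survival(t, e)
    rows = []
    for et in event_times:
        cases = (t == et) & e
        controls = t > et
        if cases.sum() == 0 or controls.sum() == 0:
            continue
        rc, rk = r[cases], r[controls]
        wins = np.sum(rc[:, None] > rk[None, :]) + 0.5 * np.sum(rc[:, None] == rk[None, :])
        auc_t = float(wins) / (cases.sum() * controls.sum())
        g = float(G.survival_function_at_times(max(et - 1e-9, 0.0)).iloc[0])
        weight = cases.sum() * controls.sum() / max(g, 1e-12) ** 2
        rows.append((float(et), auc_t, float(weight)))
    curve = pd.DataFrame(rows, columns=["time", "auc", "weight"])
    summary = float(np.average(curve["auc"], weights=curve["weight"]))
    return curve, summary


def cross_validate(data: pd.DataFrame, duration_col: str, event_col: str,
                   candidates: list[str], folds: int = 5, seed: int = 0,
                   select: bool = True) -> tuple[float, float]:
    """Event-stratified k-fold cross-validated concordance of the full
    selection + fit pipeline.  Returns (mean CI, SE over folds)."""
    n = len(data)
    if n < folds:
        raise ValueError("not enough samples for the requested folds")
    rng = np.random.default_rng(seed)
    e = data[event_col].to_numpy(bool)
    fold_of = np.empty(n, dtype=int)
    for stratum in (e, ~e):
        idx = np.where(stratum)[0]
        rng.shuffle(idx)
        fold_of[idx] = np.arange(idx.size) % folds
    if any((e & (fold_of == f)).sum() == 0 for f in range(folds)):
        raise ValueError("a fold has no events even after stratification")
    cis = []
    for f in range(folds):
        train = data.iloc[fold_of != f]
        test = data.iloc[fold_of == f]
        if select:
            fit = backward_select(train, duration_col, event_col, candidates)
            if not fit.predictors:
                cis.append(0.5)
                continue
        else:
            fit = cox_fit(train, duration_col, event_col, candidates)
        ci, _ = concordance(fit, test)
        cis.append(ci)
    cis = np.asarray(cis)
    return float(cis.mean()), float(cis.std(ddof=1) / np.sqrt(folds))


def compare_models(fit_a: CoxFit, fit_b: CoxFit) -> tuple[float, float]:
    """Likelihood-ratio chi-square test of nested Cox fits (A within B)."""
    if not set(fit_a.predictors) <= set(fit_b.predictors):
        raise ValueError("model A is not nested in model B")
    df = fit_b.n_params - fit_a.n_params
    statistic = 2.0 * (fit_b.loglik - fit_a.loglik)
    if df == 0:
        return 0.0, 1.0
    statistic = max(statistic, 0.0)
    return float(statistic), float(stats.chi2.sf(statistic, df))
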
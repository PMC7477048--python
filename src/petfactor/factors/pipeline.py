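"""End-to-end factor pipeline: filter -> z-score -> regularize -> fit ->
rotate -> score, with training-frozen transforms for validation cohorts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fa import FactorModel, guttman_dimension, ml_factor_analysis, rotate, score
from .redundancy import RedundancyResult, redundancy_filter
from .regularize import RegularizedCorrelation, ridge_correlation

logger = logging.getLogger(__name__)


@dataclass
class ZScorer:
    """Column-wise standardization with stored training means/sds (ddof=1)."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "ZScorer":
        sds = table.std(ddof=1)
        if (sds == 0).any():
            bad = list(sds.index[sds == 0])
            raise ValueError(f"constant columns cannot be z-scored: {bad}")
        return cls(means=table.mean(), sds=sds)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.means.index if c not in table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return (table[self.means.index] - self.means) / self.sds


def zscore(table: pd.DataFrame) -> tuple[pd.DataFrame, ZScorer]:
    scaler = ZScorer.fit(table)
    return scaler.transform(table), scaler


@dataclass
class FactorPipelineResult:
    redundancy: RedundancyResult
    scaler: ZScorer
    regularized: RegularizedCorrelation
    model: FactorModel               # rotated
    scores: pd.DataFrame             # training-cohort factor scores

    @property
    def factor_names(self) -> list[str]:
        return [f"factor_{j + 1}" for j in range(self.model.k)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained": self.redundancy.retained,
                "threshold": self.redundancy.threshold,
                "means": self.scaler.means.to_dict(),
                "sds": self.scaler.sds.to_dict(),
                "penalty": self.regularized.penalty,
                "R_reg": self.regularized.R_reg.tolist(),
                "k": self.model.k,
                "loadings": self.model.loadings.tolist(),
                "uniqueness": self.model.uniqueness.tolist(),
                "explained_covariation": self.model.explained_covariation,
            },
            indent=1,
        )


def run_pipeline(table: pd.DataFrame, threshold: float = 0.95,
                 penalty_grid: np.ndarray | None = None, folds: int = 5,
                 seed: int = 0, k: int | None = None, max_k: int | None = None,
                 rotation: str = "varimax",
                 fa_max_iter: int = 10_000) -> FactorPipelineResult:
    """Run the four compression steps on a training feature table.

    ``k=None`` selects the dimension by the Guttman bound (eigenvalues of
    the regularized correlation matrix strictly above 1, optionally capped
    at ``max_k``).
    """
    red = redundancy_filter(table, threshold=threshold)
    kept = table[red.retained]
    standardized, scaler = zscore(kept)
    reg = ridge_correlation(standardized, penalty_grid=penalty_grid,
                            folds=folds, seed=seed)
    if k is None:
        k = guttman_dimension(reg.R_reg, max_k=max_k)
        logger.info("Guttman bound selected k=%d factors", k)
    # Heywood-adjacent solutions converge slowly; allow the EM-style
    # iteration a generous cap at pipeline level
    unrotated = ml_factor_analysis(reg.R_reg, k, feature_names=red.retained,
                                   max_iter=fa_max_iter)
    model = rotate(unrotated, method=rotation)
    F = score(standardized.to_numpy(), model, reg.R_reg)
    scores = pd.DataFrame(F, index=table.index,
                          columns=[f"factor_{j + 1}" for j in range(k)])
    logger.info(
        "factor pipeline: %d -> %d features, k=%d, explained covariation %.3f",
        table.shape[1], len(red.retained), k, model.explained_covariation,
    )
    return FactorPipelineResult(
        redundancy=red, scaler=scaler, regularized=reg, model=model, scores=scores
    )


def apply_pipeline(table: pd.DataFrame, fitted: FactorPipelineResult) -> pd.DataFrame:
    """Score a new cohort with training-frozen transforms (feature set,
    z-score parameters, regularized correlation, loadings)."""
    standardized = fitted.scaler.transform(table)
    F = score(standardized.to_numpy(), fitted.model, fitted.regularized.R_reg)
    return pd.DataFrame(F, index=table.index, columns=fitted.factor_names)
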
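"""Feature tables with a known orthogonal latent-factor structure.

Data are generated from the common factor model

    x = L f + sqrt(psi) * e,     f ~ N(0, I_k),  e ~ N(0, I_p)

with loadings ``L`` (p x k) and uniquenesses ``psi`` (communality +
uniqueness = 1 per feature), then z-scored.  Optionally, near-duplicate
"clone" columns are appended (population correlation ``clone_r`` with their
parent) to emulate the redundancy of real radiomic feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FactorGroundTruth:
    """Ground truth of a generated table; filled in by the generator."""

    n_patients: int
    loading_matrix: np.ndarray            # p x k, entries in [-1, 1]
    uniqueness: np.ndarray | None = None  # defaults to 1 - communality
    n_redundant_clones: int = 0
    clone_r: float = 0.99
    seed: int = 0
    # outputs
    true_scores: np.ndarray | None = None
    clone_parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loading_matrix = np.atleast_2d(np.asarray(self.loading_matrix, float))
        if np.any(np.abs(self.loading_matrix) > 1):
            raise ValueError("loadings must lie in [-1, 1]")
        communality = np.sum(self.loading_matrix ** 2, axis=1)
        if self.uniqueness is None:
            self.uniqueness = 1.0 - communality
        else:
            self.uniqueness = np.asarray(self.uniqueness, float)
            if not np.allclose(communality + self.uniqueness, 1.0, atol=1e-8):
                raise ValueError("communality + uniqueness must equal 1 per feature")
        if np.any(self.uniqueness < 0):
            raise ValueError(
                "negative uniqueness: implied correlation not positive definite"
            )

    @property
    def n_features(self) -> int:
        return self.loading_matrix.shape[0]

    @property
    def k_factors(self) -> int:
        return self.loading_matrix.shape[1]

    @property
    def population_correlation(self) -> np.ndarray:
        L = self.loading_matrix
        return L @ L.T + np.diag(self.uniqueness)


def simple_structure_loadings(p: int, k: int, communality_range=(0.6, 0.9),
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Loadings with perfect simple structure: each feature loads on exactly
    one factor, features spread evenly over factors."""
    rng = rng or np.random.default_rng(0)
    L = np.zeros((p, k))
    assign = np.arange(p) % k
    comm = rng.uniform(*communality_range, size=p)
    signs = rng.choice([-1.0, 1.0], size=p)
    L[np.arange(p), assign] = signs * np.sqrt(comm)
    return L


def generate_feature_table(gt: FactorGroundTruth) -> tuple[pd.DataFrame, FactorGroundTruth]:
    """Draw a standardized feature table; ground truth is filled in place."""
    if gt.k_factors >= gt.n_features:
        raise ValueError("k_factors must be smaller than n_features")
    rng = np.random.default_rng(gt.seed)
    n, p, k = gt.n_patients, gt.n_features, gt.k_factors
    scores = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, p))
    X = scores @ gt.loading_matrix.T + noise * np.sqrt(gt.uniqueness)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    names = [f"feat_{i:03d}" for i in range(p)]
    df = pd.DataFrame(X, columns=names)

    clone_parents: dict[str, str] = {}
    if gt.n_redundant_clones > 0:
        parents = rng.choice(p, size=gt.n_redundant_clones, replace=False)
        rho = gt.clone_r
        for c, pi in enumerate(parents):
            col = rho * X[:, pi] + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
            col = (col - col.mean()) / col.std(ddof=1)
            name = f"clone_{c:03d}_of_{names[pi]}"
            df[name] = col
            clone_parents[name] = names[pi]

    gt.true_scores = scores
    gt.clone_parents = clone_parents
    return df, gt
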
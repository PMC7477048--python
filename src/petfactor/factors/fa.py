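"""Maximum-likelihood factor analysis of a correlation matrix, varimax
rotation, Guttman dimensionality, and regression factor scores.

The fit iterates the eigen-based conditional-maximization step: given
uniquenesses Psi, the loadings maximizing the Gaussian likelihood are

    Lambda = Psi^(1/2) V_k (Gamma_k - I)^(1/2)

with V_k, Gamma_k the leading eigenpairs of Psi^(-1/2) R Psi^(-1/2);
Psi is then updated from diag(R - Lambda Lambda').  Uniquenesses hitting
the Heywood floor (0.005) are clamped and flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

HEYWOOD_FLOOR = 0.005


class FactorConvergenceError(RuntimeError):
    """Raised when the ML iteration fails to converge; carries the last
    iterate in ``last_model``."""

    def __init__(self, message: str, last_model: "FactorModel"):
        super().__init__(message)
        self.last_model = last_model


@dataclass
class FactorModel:
    k: int
    loadings: np.ndarray                 # p x k
    uniqueness: np.ndarray               # p
    rotation: np.ndarray                 # k x k orthogonal (identity if unrotated)
    feature_names: list[str] = field(default_factory=list)
    heywood: list[int] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings ** 2, axis=1)

    @property
    def explained_covariation(self) -> float:
        """Proportion of the total standardized variance captured by the
        common factors (sum of communalities / p)."""
        return float(self.communalities.sum() / self.loadings.shape[0])

    def implied_correlation(self) -> np.ndarray:
        return self.loadings @ self.loadings.T + np.diag(self.uniqueness)


def guttman_dimension(R_reg: np.ndarray, max_k: int | None = None) -> int:
    """Guttman's (weakest) lower bound: eigenvalues strictly greater than 1."""
    eig = np.linalg.eigvalsh(R_reg)
    k = int(np.sum(eig > 1.0))
    if k == 0:
        raise ValueError("no eigenvalue exceeds 1: no common factor structure")
    if max_k is not None:
        k = min(k, max_k)
    return k


def ml_factor_analysis(R_reg: np.ndarray, k: int, feature_names=None,
                       max_iter: int = 500, tol: float = 1e-6) -> FactorModel:
    """Fit loadings and uniquenesses to a (regularized) correlation matrix."""
    R = np.asarray(R_reg, float)
    p = R.shape[0]
    if not (1 <= k < p):
        raise ValueError("need 1 <= k < p")
    feature_names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(p)
    ]
    # initialize from squared multiple correlations
    try:
        psi = np.clip(1.0 / np.diag(np.linalg.inv(R)), HEYWOOD_FLOOR, 1.0)
    except np.linalg.LinAlgError:
        psi = np.full(p, 0.5)

    L = np.zeros((p, k))
    heywood: set[int] = set()
    for it in range(1, max_iter + 1):
        d = 1.0 / np.sqrt(psi)
        Rs = R * np.outer(d, d)
        w, V = np.linalg.eigh(Rs)
        w, V = w[::-1][:k], V[:, ::-1][:, :k]
        gamma = np.sqrt(np.clip(w - 1.0, 0.0, None))
        L_new = np.sqrt(psi)[:, None] * V * gamma[None, :]
        psi_new = np.diag(R) - np.sum(L_new ** 2, axis=1)
        low = psi_new < HEYWOOD_FLOOR
        heywood |= set(np.where(low)[0].tolist())
        psi_new = np.clip(psi_new, HEYWOOD_FLOOR, None)
        delta = max(np.abs(L_new - L).max(), np.abs(psi_new - psi).max())
        L, psi = L_new, psi_new
        if delta < tol:
            if heywood:
                logger.info("Heywood cases clamped for features %s",
                            sorted(heywood))
            return FactorModel(k=k, loadings=L, uniqueness=psi,
                               rotation=np.eye(k), feature_names=feature_names,
                               heywood=sorted(heywood), n_iter=it, converged=True)
    last = FactorModel(k=k, loadings=L, uniqueness=psi, rotation=np.eye(k),
                       feature_names=feature_names, heywood=sorted(heywood),
                       n_iter=max_iter, converged=False)
    raise FactorConvergenceError(
        f"factor analysis did not converge in {max_iter} iterations "
        f"(last step change {delta:.2e})", last)


def _varimax_rotation(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    p, k = L.shape
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag(np.sum(Lr ** 2, axis=0)) / p)
        )
        R = u @ vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    return R


def rotate(model: FactorModel, method: str = "varimax") -> FactorModel:
    """Orthogonal rotation to simple structure; communalities are invariant.

    Columns are re-ordered by explained variance and their signs fixed so
    the largest-|loading| entry of each column is positive.
    """
    if method not in ("varimax", "none"):
        raise ValueError(f"unsupported rotation {method!r}")
    k = model.k
    if k == 1 or method == "none":
        R = np.eye(k)
    else:
        R = _varimax_rotation(model.loadings)
    L = model.loadings @ R
    # order by sum of squared loadings, descending
    order = np.argsort(-np.sum(L ** 2, axis=0), kind="stable")
    L = L[:, order]
    R = R[:, order]
    # sign convention
    for j in range(k):
        i_max = int(np.argmax(np.abs(L[:, j])))
        if L[i_max, j] < 0:
            L[:, j] *= -1.0
            R[:, j] *= -1.0
    return FactorModel(
        k=k, loadings=L, uniqueness=model.uniqueness, rotation=R,
        feature_names=model.feature_names, heywood=model.heywood,
        n_iter=model.n_iter, converged=model.converged,
    )


def score_weights(model: FactorModel, R_reg: np.ndarray) -> np.ndarray:
    """Regression (Thomson) scoring weights W = R_reg^{-1} Lambda."""
    return np.linalg.solve(R_reg, model.loadings)


def score(standardized: np.ndarray, model: FactorModel, R_reg: np.ndarray) -> np.ndarray:
    """Thomson factor scores F = X R_reg^{-1} Lambda for standardized X."""
    X = np.asarray(standardized, float)
    if X.shape[1] != model.loadings.shape[0]:
        raise ValueError(
            f"data has {X.shape[1]} features, model expects {model.loadings.shape[0]}"
        )
    return X @ score_weights(model, R_reg)


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> tuple[float, np.ndarray]:
    """Tucker congruence between factor-loading matrices, after matching
    columns (order and sign are indeterminate in factor solutions).

    Returns the mean absolute congruence over matched columns and the
    per-column values.
    """
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    na = A / np.linalg.norm(A, axis=0, keepdims=True)
    nb = B / np.linalg.norm(B, axis=0, keepdims=True)
    C = np.abs(na.T @ nb)
    rows, cols = linear_sum_assignment(-C)
    per_factor = C[rows, cols]
    return float(per_factor.mean()), per_factor
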
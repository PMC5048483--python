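"""STATIS combination of M configurations into a compromise.

Each configuration's score matrix X_n is turned into the individuals x
individuals cross-product W_n = X_n X_n^T, which is invariant to rotation
and reflection of the scores. The RV coefficient between every pair of W_n
gives a nonnegative matrix R; its leading (Perron) eigenvector, normalised
to sum to one, supplies the weights alpha_n; the eigendecomposition of the
weighted sum W_c = sum alpha_n W_n yields the compromise configuration.
Projecting each W_n onto the compromise axes gives the per-configuration
trajectories (M points per individual) used downstream for uncertainty
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Configuration

__all__ = ["CompromiseResult", "cross_product", "rv_coefficient", "statis_compromise"]


@dataclass
class CompromiseResult:
    rv_matrix: np.ndarray          # M x M, symmetric, unit diagonal
    alpha: np.ndarray              # M nonnegative weights summing to 1
    compromise_scores: np.ndarray  # I x d principal coordinates of W_c
    compromise_eigenvalues: np.ndarray
    trajectories: list[np.ndarray]  # M matrices, I x d
    individual_ids: list[str]

    def as_configuration(self) -> Configuration:
        return Configuration(
            scores=self.compromise_scores,
            eigenvalues=self.compromise_eigenvalues,
            individual_ids=list(self.individual_ids),
        )


def cross_product(config: Configuration | np.ndarray) -> np.ndarray:
    """W = X X^T, the symmetric PSD matrix of inner products between
    individuals' score vectors."""
    X = config.scores if isinstance(config, Configuration) else np.asarray(config, float)
    return X @ X.T


def rv_coefficient(W_j: np.ndarray, W_k: np.ndarray) -> float:
    """RV coefficient (cosine) between two cross-product matrices:
    trace(W_j^T W_k) / sqrt(trace(W_j^T W_j) trace(W_k^T W_k)).

    Symmetric, invariant to positive scaling of either argument, and in
    [0, 1] for PSD arguments. Raises on an all-zero matrix.
    """
    W_j = np.asarray(W_j, float)
    W_k = np.asarray(W_k, float)
    if W_j.shape != W_k.shape:
        raise ValueError("cross-product matrices must have identical shape")
    num = float(np.sum(W_j * W_k))  # trace(W_j^T W_k) for symmetric W
    den_j = float(np.sum(W_j * W_j))
    den_k = float(np.sum(W_k * W_k))
    if den_j == 0.0 or den_k == 0.0:
        raise ValueError("RV coefficient undefined for an all-zero matrix")
    return num / np.sqrt(den_j * den_k)


def _sign_fix_columns(U: np.ndarray) -> np.ndarray:
    for k in range(U.shape[1]):
        idx = int(np.argmax(np.abs(U[:, k])))
        if U[idx, k] < 0:
            U[:, k] = -U[:, k]
    return U


def statis_compromise(configs: list[Configuration], d: int = 2) -> CompromiseResult:
    """Combine M configurations into the STATIS compromise.

    Configurations are used as-is (MFA scores are already centred). With a
    single configuration the compromise reproduces it up to component sign;
    with M identical configurations alpha is uniform.
    """
    if not configs:
        raise ValueError("need at least one configuration")
    ids = configs[0].individual_ids
    for c in configs[1:]:
        if c.individual_ids != ids:
            raise ValueError("configurations must share the same individuals in order")
        if c.scores.shape != configs[0].scores.shape:
            raise ValueError("configurations must share dimensionality")
    if d < 1 or d > len(ids):
        raise ValueError(f"invalid compromise dimensionality d={d}")

    M = len(configs)
    Ws = [cross_product(c) for c in configs]
    R = np.eye(M)
    for j in range(M):
        for k in range(j + 1, M):
            R[j, k] = R[k, j] = rv_coefficient(Ws[j], Ws[k])

    evals, evecs = np.linalg.eigh(R)
    u = evecs[:, -1]
    if u.sum() < 0:  # Perron direction defined up to sign
        u = -u
    u = np.clip(u, 0.0, None)  # numeric noise on a nonnegative eigenvector
    alpha = u / u.sum()

    W_c = np.zeros_like(Ws[0])
    for a, W in zip(alpha, Ws):
        W_c += a * W

    lam, U = np.linalg.eigh(W_c)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    U = _sign_fix_columns(U[:, order].copy())
    k = min(d, len(lam))
    scores = np.zeros((len(ids), d))
    eigenvalues = np.zeros(d)
    scores[:, :k] = U[:, :k] * np.sqrt(lam[:k])
    eigenvalues[:k] = lam[:k]

    # trajectories: supplementary projection W_n U_c Lambda_c^{-1/2}
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(lam[:k] > 1e-12 * max(lam[0], 1.0), 1.0 / np.sqrt(lam[:k]), 0.0)
    proj = U[:, :k] * inv_sqrt
    trajectories = []
    for W in Ws:
        t = np.zeros((len(ids), d))
        t[:, :k] = W @ proj
        trajectories.append(t)

    return CompromiseResult(
        rv_matrix=R,
        alpha=alpha,
        compromise_scores=scores,
        compromise_eigenvalues=eigenvalues,
        trajectories=trajectories,
        individual_ids=list(ids),
    )
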
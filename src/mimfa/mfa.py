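"""Multiple factor analysis (MFA) on a complete multi-table dataset.

MFA is a weighted global PCA: each table is preprocessed (centred and, by
default, scaled to unit variance), its first PCA eigenvalue lambda_1^j is
computed, every variable of table j is weighted by 1/sqrt(lambda_1^j), and a
single PCA is run on the column-wise concatenation of the weighted tables.
The weighting removes each table's own dominant variance so that no single
table can dominate the first global dimension.

Conventions follow the French-school PCA: uniform row weights 1/I, so
eigenvalues are singular values squared divided by I, and variables are
standardised with the population (ddof=0) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import Configuration, MultiOmicsSet, OmicsTable

__all__ = ["PreprocessSpec", "preprocess_table", "table_first_eigenvalue", "mfa"]


@dataclass(frozen=True)
class PreprocessSpec:
    """Variable preprocessing applied within each table.

    ``center`` is always required (PCA is defined on centred data);
    ``scale_unit_variance`` standardises every variable to unit variance
    and is on by default, matching the common MFA convention for
    quantitative variable groups.
    """

    center: bool = True
    scale_unit_variance: bool = True

    def __post_init__(self) -> None:
        if not self.center:
            raise ValueError("PCA requires centred variables; center must be True")


def preprocess_table(values: np.ndarray, spec: PreprocessSpec, variable_ids=None) -> np.ndarray:
    """Centre (and optionally standardise, ddof=0) the columns of a complete matrix."""
    X = np.asarray(values, dtype=float)
    if np.isnan(X).any():
        raise ValueError("preprocessing requires a fully observed matrix")
    X = X - X.mean(axis=0)
    if spec.scale_unit_variance:
        sd = X.std(axis=0, ddof=0)
        zero = np.nonzero(sd == 0)[0]
        if zero.size:
            names = (
                [variable_ids[k] for k in zero] if variable_ids is not None else list(zero)
            )
            raise ValueError(f"zero-variance variable(s) cannot be scaled: {names}")
        X = X / sd
    return X


def table_first_eigenvalue(table: OmicsTable, spec: PreprocessSpec | None = None) -> float:
    """Largest eigenvalue lambda_1^j of the PCA of one preprocessed table.

    The table must be fully observed with at least two individuals.
    Eigenvalues are on the covariance scale: singular value squared / I.
    """
    spec = spec or PreprocessSpec()
    if not table.observed_mask.all():
        raise ValueError(
            f"table {table.name!r} has missing rows; MFA operates on complete data "
            "(impute first)"
        )
    if table.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    X = preprocess_table(table.values, spec, table.variable_ids)
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[0] ** 2 / X.shape[0])


def _sign_fix(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign: per component, the loading of largest absolute
    value is made positive; ties broken by earliest variable index."""
    for k in range(V.shape[1]):
        col = V[:, k]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            V[:, k] = -col
            U[:, k] = -U[:, k]
    return U, V


def mfa(
    dataset: MultiOmicsSet,
    d: int = 2,
    spec: PreprocessSpec | None = None,
) -> Configuration:
    """Run MFA on a complete multi-table dataset and return the d-dimensional
    configuration (principal coordinates of the individuals).

    Raises if any table has missing rows (the caller should impute first) or
    if ``d`` exceeds min(I-1, total number of variables). If ``d`` exceeds
    the numerical rank, the result is padded with zero-eigenvalue components
    and a warning is emitted so downstream shapes stay stable.
    """
    spec = spec or PreprocessSpec()
    if d < 1:
        raise ValueError("d must be a positive integer")
    for t in dataset.tables:
        if not t.observed_mask.all():
            raise ValueError(
                f"table {t.name!r} has missing rows; run hot-deck, mean or iterative "
                "imputation before MFA"
            )
    I = dataset.n_individuals
    p_total = sum(t.n_variables for t in dataset.tables)
    if d > min(I - 1, p_total):
        raise ValueError(f"d={d} exceeds min(I-1, total variables)={min(I - 1, p_total)}")

    blocks: list[np.ndarray] = []
    table_weights: dict[str, dict[str, float]] = {}
    for t in dataset.tables:
        X = preprocess_table(t.values, spec, t.variable_ids)
        lam1 = float(np.linalg.svd(X, compute_uv=False)[0] ** 2 / I)
        blocks.append(X / np.sqrt(lam1))
        table_weights[t.name] = {"lambda1": lam1, "weight": 1.0 / np.sqrt(lam1)}
    K = np.hstack(blocks)

    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    eigvals = s**2 / I
    rank = int(np.sum(s > s[0] * max(I, K.shape[1]) * np.finfo(float).eps)) if s.size else 0
    U, V = _sign_fix(U, Vt.T)
    scores = U * s  # principal coordinates

    if d > rank:
        warnings.warn(
            f"requested d={d} exceeds numerical rank {rank}; padding with "
            "zero-eigenvalue components",
            RuntimeWarning,
            stacklevel=2,
        )
    out_scores = np.zeros((I, d))
    out_ev = np.zeros(d)
    keep = min(d, rank)
    out_scores[:, :keep] = scores[:, :keep]
    out_ev[:keep] = eigvals[:keep]
    return Configuration(
        scores=out_scores,
        eigenvalues=out_ev,
        individual_ids=list(dataset.individual_ids),
        table_weights=table_weights,
    )
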
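"""Orthogonal matching pursuit (OMP).

Greedy sparse coding: at each step the atom most correlated with the current
residual joins the support, and the coefficients are re-fitted by least
squares on the whole support. Used both for sparse coding inside K-SVD and
for the reconstruction-error classifier.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError


def omp(dictionary: np.ndarray, y: np.ndarray, sparsity: int,
        tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray, float]:
    """Code ``y`` over unit-norm-atom ``dictionary`` (p x d) with at most
    ``sparsity`` atoms.

    Returns ``(coefficients, support, squared_residual)`` where
    ``coefficients`` is dense length-d.
    """
    Q = np.asarray(dictionary, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if Q.ndim != 2 or Q.shape[0] != y.shape[0]:
        raise ShapeError("dictionary/signal dimension mismatch")
    if not np.any(Q):
        raise ShapeError("all-zero dictionary")
    d = Q.shape[1]
    sparsity = min(int(sparsity), d)
    support: list[int] = []
    beta = np.zeros(d)
    residual = y.copy()
    coef_s = np.zeros(0)
    for _ in range(sparsity):
        corr = Q.T @ residual
        corr[support] = 0.0
        j = int(np.argmax(np.abs(corr)))
        if abs(corr[j]) <= tol:
            break
        support.append(j)
        Qs = Q[:, support]
        coef_s, *_ = np.linalg.lstsq(Qs, y, rcond=None)
        residual = y - Qs @ coef_s
        if residual @ residual <= tol:
            break
    if support:
        beta[support] = coef_s
    return beta, np.asarray(support, dtype=int), float(residual @ residual)


def omp_batch(dictionary: np.ndarray, Y: np.ndarray, sparsity: int
              ) -> np.ndarray:
    """Code every column of ``Y`` (p x n); returns the code matrix (d x n)."""
    Y = np.asarray(Y, dtype=np.float64)
    codes = np.zeros((dictionary.shape[1], Y.shape[1]))
    for i in range(Y.shape[1]):
        codes[:, i], _, _ = omp(dictionary, Y[:, i], sparsity)
    return codes
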
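"""Small numeric helpers used throughout the package."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DataError


def standardize_vector(x, ddof: int = 0) -> np.ndarray:
    """Return x centered to mean 0 and scaled to SD 1."""
    x = np.asarray(x, dtype=float).ravel()
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("cannot standardize a zero-variance vector")
    return (x - x.mean()) / sd


def pearson_fisher(x, y) -> tuple:
    """Pearson correlation with a two-sided Fisher-z p-value.

    The Fisher transform z = atanh(r) is approximately normal with SD
    1/sqrt(n-3) under the null, giving p = 2*Phi(-|z|*sqrt(n-3)).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if n != len(y):
        raise DataError("length mismatch in correlation")
    if n < 4:
        raise DataError("need at least 4 observations for a Fisher-z p-value")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(r_c) * np.sqrt(n - 3)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return r, max(p, np.finfo(float).tiny)


def orth_basis(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of X (SVD-based)."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return np.zeros((X.shape[0], 0))
    keep = s > rtol * s[0]
    return U[:, keep]


def amari_index(W: np.ndarray, A: np.ndarray) -> float:
    """Normalized Amari distance between an unmixing W and true mixing A.

    Zero iff W @ A is a scaled permutation; bounded by 1. Invariant to
    permutation and scaling of the recovered components.
    """
    P = np.abs(np.asarray(W) @ np.asarray(A))
    m = P.shape[0]
    if m == 1:
        return 0.0
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row + col) / (2.0 * m * (m - 1)))
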
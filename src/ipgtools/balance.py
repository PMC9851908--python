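"""Bin-level filtering and iterative-correction (ICE) matrix balancing."""
from __future__ import annotations

import numpy as np

from .core import ContactMatrix

__all__ = ["filter_bins", "iterative_correction", "BalanceError"]


class BalanceError(RuntimeError):
    """Balancing failed; carries iteration diagnostics."""

    def __init__(self, message, n_iter=None, variance=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.variance = variance


def filter_bins(m: ContactMatrix, mad_threshold: float = 5.0,
                min_nnz: int = 2) -> ContactMatrix:
    """Mark low-coverage bins invalid (MAD-max filter plus a nonzero count floor).

    A bin is invalidated when its total raw coverage falls more than
    ``mad_threshold`` median absolute deviations below the median coverage of
    currently valid bins, or when it has fewer than ``min_nnz`` nonzero
    pixels. Matrix values are untouched.
    """
    coverage = m.values.sum(axis=1)
    nnz = (m.values != 0).sum(axis=1)
    valid = m.bins.valid & (nnz >= min_nnz) & (coverage > 0)
    cov_valid = coverage[valid]
    if cov_valid.size and np.isfinite(mad_threshold):
        med = np.median(cov_valid)
        mad = np.median(np.abs(cov_valid - med))
        valid &= coverage >= med - mad_threshold * mad
    if not valid.any():
        raise ValueError("empty matrix after filtering")
    out = m.copy()
    out.bins = m.bins.with_valid(valid)
    return out


def _ice(values: np.ndarray, valid: np.ndarray, tol: float, max_iter: int):
    """Core ICE loop on the valid submatrix.

    Returns (balanced_submatrix_embedded, weights) where marginals over valid
    bins are equal; convergence criterion is the relative variance of the
    nonzero marginals.
    """
    n = values.shape[0]
    sub = values[np.ix_(valid, valid)].astype(float)
    w = np.ones(sub.shape[0])
    var = np.inf
    for it in range(max_iter):
        marg = (sub * w[None, :]).T @ w  # marginals of diag(w) M diag(w)
        nz = marg > 0
        mean = marg[nz].mean()
        var = float(np.var(marg[nz] / mean))
        if var < tol:
            break
        adj = np.where(nz, marg / mean, 1.0)
        w = w / np.sqrt(adj)
    else:
        raise BalanceError(
            f"iterative correction did not converge in {max_iter} iterations "
            f"(marginal variance {var:.3g} > tol {tol:.3g})",
            n_iter=max_iter, variance=var)
    balanced = sub * np.outer(w, w)
    out = np.zeros((n, n))
    out[np.ix_(valid, valid)] = balanced
    weights = np.full(n, np.nan)
    weights[valid] = w
    return out, weights


def iterative_correction(m: ContactMatrix, tol: float = 1e-5,
                         max_iter: int = 300) -> ContactMatrix:
    """Balance the matrix so valid-bin marginals are equal (ICE).

    Invalid bins get NaN weight and zeroed rows/columns in the balanced
    values. Idempotent within tolerance. Raises :class:`BalanceError` with
    iteration diagnostics on non-convergence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    valid = m.bins.valid
    if not valid.any():
        raise ValueError("empty matrix after filtering")
    balanced, weights = _ice(m.values, valid, tol, max_iter)
    return ContactMatrix(m.bins, balanced, weights=weights, balanced=True)
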
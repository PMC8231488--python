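"""Shared linear-algebra helpers: symmetrization, jitter regularization, SPD roots.

All covariance/information matrices in this package are kept numerically
symmetric by explicit symmetrization after every update, and inverted only
through :func:`spd_inverse`, which applies a relative jitter when the matrix is
close to singular and raises an informative error when it is genuinely
rank-deficient.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "NotPositiveDefiniteError",
    "symmetrize",
    "spd_sqrt",
    "spd_inverse",
    "regularize_spd",
    "floor_covariance",
]

# Relative jitter policy: add lam*I with lam = JITTER_REL * trace/n whenever the
# smallest eigenvalue falls below EIG_TOL_REL times the largest.
JITTER_REL = 1e-9
EIG_TOL_REL = 1e-12


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Raised when a matrix required to be positive definite is not."""


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """Return (M + M.T)/2, removing floating-point asymmetry drift."""
    matrix = np.asarray(matrix, dtype=float)
    return 0.5 * (matrix + matrix.T)


def regularize_spd(
    matrix: np.ndarray,
    name: str = "matrix",
    abs_floor: float = 0.0,
) -> np.ndarray:
    """Symmetrize and, if near-singular, jitter a covariance-like matrix.

    Parameters
    ----------
    matrix
        Square symmetric (up to roundoff) matrix expected to be positive
        definite after regularization.
    name
        Label used in error messages.
    abs_floor
        Optional absolute jitter added when the relative jitter is itself zero
        (e.g. an exactly-zero residue covariance). Zero disables the fallback,
        in which case a degenerate matrix raises.

    Raises
    ------
    NotPositiveDefiniteError
        If the matrix cannot be made positive definite; the message suggests
        jitter regularization of the offending statistic.
    """
    sym = symmetrize(matrix)
    eigvals = np.linalg.eigvalsh(sym)
    largest = eigvals[-1]
    n = sym.shape[0]
    if eigvals[0] > EIG_TOL_REL * max(largest, 0.0) and eigvals[0] > 0.0:
        return sym
    lam = JITTER_REL * np.trace(sym) / n
    if lam <= 0.0 and abs_floor > 0.0:
        warnings.warn(
            f"{name} is numerically zero; applying absolute jitter floor "
            f"{abs_floor:g}*I.",
            stacklevel=2,
        )
        lam = abs_floor
    if lam <= 0.0:
        raise NotPositiveDefiniteError(
            f"{name} is rank-deficient (eigenvalues {eigvals}); add jitter "
            "regularization (lambda*I with small positive lambda) to the "
            "residue covariance, or supply more varied data."
        )
    sym = sym + lam * np.eye(n)
    eigvals = np.linalg.eigvalsh(sym)
    if eigvals[0] <= 0.0:
        raise NotPositiveDefiniteError(
            f"{name} remains non-positive-definite after jitter (eigenvalues "
            f"{eigvals}); increase the jitter or inspect the data."
        )
    return sym


def spd_inverse(matrix: np.ndarray, name: str = "matrix", abs_floor: float = 0.0) -> np.ndarray:
    """Inverse of a symmetric positive definite matrix via eigendecomposition.

    The input is regularized with :func:`regularize_spd` first, so the returned
    inverse satisfies ``inv @ regularized == I`` to high accuracy and is exactly
    symmetric.
    """
    sym = regularize_spd(matrix, name=name, abs_floor=abs_floor)
    w, u = np.linalg.eigh(sym)
    inv = (u / w) @ u.T
    return symmetrize(inv)


def spd_sqrt(matrix: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Symmetric positive definite square root S with S @ S = M.

    Being symmetric, S satisfies both S @ S.T = M and S.T @ S = M, which is the
    property the whitened augmented regression relies on.
    """
    sym = symmetrize(matrix)
    w, u = np.linalg.eigh(sym)
    if w[0] <= 0.0:
        raise NotPositiveDefiniteError(
            f"{name} is not positive definite (smallest eigenvalue {w[0]:g}); "
            "cannot form a whitening factor."
        )
    root = (u * np.sqrt(w)) @ u.T
    return symmetrize(root)


def floor_covariance(matrix: np.ndarray, eps: float, name: str = "covariance") -> np.ndarray:
    """Floor the eigenvalues of a covariance matrix at ``eps``.

    Used for residue covariances of very accurate (e.g. constant-target)
    observers, where the raw sample covariance can be numerically zero.
    """
    sym = symmetrize(matrix)
    w, u = np.linalg.eigh(sym)
    if w[0] >= eps:
        return sym
    warnings.warn(
        f"{name} has eigenvalues below the configured floor {eps:g}; flooring.",
        stacklevel=2,
    )
    w = np.maximum(w, eps)
    return symmetrize((u * w) @ u.T)
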
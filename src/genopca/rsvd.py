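"""Randomized SVD for the top-k eigenvectors of X^T X.

The range-finder recipe: draw a Gaussian test matrix with 2k columns,
apply q rounds of power iteration to sharpen the spectrum, orthonormalize
to get Q, project to a small matrix B, and take B's exact (truncated)
SVD.  Because only the eigenvectors of the m×m similarity matrix
S = X^T X are wanted — vectors of length m — the sketch is run on X^T,
so Q lives in the m-dimensional sample space and U = Q·Ũ ∈ R^{m×k}
holds the principal components directly:

    Ω ~ N(0,1)^{n×2k}
    Y = (X^T X)^q X^T Ω ∈ R^{m×2k}
    Q R = Y                        (reduced QR)
    B = Q^T X^T ∈ R^{2k×n}
    B = Ũ Σ Ṽ^T                   (small exact SVD, truncated to k)
    eigenvectors = Q Ũ_k,  eigenvalues = Σ_k²

Every product with X goes through matvec/rmatvec, so when X is a
:class:`~genopca.operators.FactoredOperator` the similarity matrix and
the dense X are never formed and the whole run costs
O(qk·nm + k²(n+m)) — linear in n and in m with the other fixed.  The
same core runs on a dense ndarray, which makes the factored path
bit-comparable to the dense path under a shared seed.

The expected rank-k reconstruction error obeys (for 2 ≤ k ≤ min(m,n)/2)

    E ‖X − U Σ V^T‖₂ ≤ [1 + 4 sqrt(2 min(m,n)/(k−1))]^{1/(2q+1)} σ_{k+1},

so larger power exponents q trade compute for accuracy; q = 2k is the
recommended default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ShapeError
from .operators import FactoredOperator

__all__ = [
    "EigenResult",
    "randomized_svd",
    "fast_eigenvectors",
    "svd_error_bound",
    "power_method",
    "reconstruct",
    "fix_signs",
]

#: eigenvalues below this (relative to the largest sketch value) count as zero
_DEGENERATE_TOL = 1e-300


@dataclass(frozen=True)
class EigenResult:
    """Top-k eigenpairs of X^T X with randomized-SVD provenance.

    ``vectors`` (m×k, orthonormal columns, each flipped so its
    largest-magnitude entry is positive) are the principal components;
    ``values`` are the matching nonincreasing eigenvalues (squared
    singular values of X).  ``left_vectors`` (n×k) complete the rank-k
    SVD X ≈ left · diag(σ) · vectorsᵀ with σ = sqrt(values).
    """

    vectors: np.ndarray
    values: np.ndarray
    k: int
    q: int
    seed: int | None
    method: str
    left_vectors: np.ndarray | None = None
    degenerate: bool = False

    @property
    def singular_values(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.values, 0.0))


def fix_signs(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each column so its largest-magnitude entry is positive.

    Eigenvectors are defined only up to a unit; this convention makes
    outputs reproducible.  Returns (flipped matrix, sign per column).
    """
    V = np.asarray(V)
    idx = np.abs(V).argmax(axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs[None, :], signs


def _check_k(k: int, n: int, m: int, q: int, allow_k1: bool) -> None:
    if q < 0:
        raise ParameterError(f"power exponent q must be >= 0, got {q}")
    lo = 1 if allow_k1 else 2
    if not (lo <= k <= 0.5 * min(n, m)):
        raise ParameterError(
            f"k={k} outside the validity range [{lo}, 0.5*min(n,m)={0.5 * min(n, m)}] "
            "(pass allow_k1=True for k=1 at your own risk)"
        )


def _rsvd_core(matmat, rmatmat, n: int, m: int, k: int, q: int, rng) -> tuple:
    ell = 2 * k
    Omega = rng.standard_normal((n, ell))
    Y = rmatmat(Omega)                      # X^T Ω, m×2k
    for _ in range(q):
        Y = rmatmat(matmat(Y))              # (X^T X) Y
    Q, _ = np.linalg.qr(Y)                  # m×2k orthonormal
    B = matmat(Q).T                         # Q^T X^T, 2k×n
    Ub, sing, Vt = np.linalg.svd(B, full_matrices=False)
    U = Q @ Ub[:, :k]                       # m×k eigenvectors of X^T X
    left = Vt[:k].T                         # n×k left singular vectors of X
    U, signs = fix_signs(U)
    left = left * signs[None, :]
    return U, sing[:k] ** 2, left


def randomized_svd(
    X: np.ndarray,
    k: int,
    q: int | None = None,
    seed: int | None = 0,
    allow_k1: bool = False,
) -> EigenResult:
    """Randomized top-k eigendecomposition of X^T X for a dense X."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ShapeError("X must be a 2-d matrix")
    n, m = X.shape
    if q is None:
        q = 2 * k
    _check_k(k, n, m, q, allow_k1)
    rng = np.random.default_rng(seed)
    U, vals, left = _rsvd_core(lambda Y: X @ Y, lambda Z: X.T @ Z, n, m, k, q, rng)
    return EigenResult(
        vectors=U, values=vals, k=k, q=q, seed=seed, method="algorithm1",
        left_vectors=left, degenerate=bool(vals.max(initial=0.0) <= _DEGENERATE_TOL),
    )


def fast_eigenvectors(
    F: FactoredOperator,
    k: int,
    q: int | None = None,
    seed: int | None = 0,
    allow_k1: bool = False,
) -> EigenResult:
    """Randomized top-k eigendecomposition of X^T X through a factored operator.

    Identical contract (and, under the same seed and q, identical output
    up to floating-point reassociation) to :func:`randomized_svd` on the
    materialized X, but every product goes through the operator's sparse
    matvec/rmatvec: neither the similarity matrix nor a dense X is ever
    formed, and auxiliary storage stays O((n+m)·k).
    """
    n, m = F.shape
    if q is None:
        q = 2 * k
    _check_k(k, n, m, q, allow_k1)
    rng = np.random.default_rng(seed)
    U, vals, left = _rsvd_core(F.matvec, F.rmatvec, n, m, k, q, rng)
    return EigenResult(
        vectors=U, values=vals, k=k, q=q, seed=seed, method="algorithm2",
        left_vectors=left, degenerate=bool(vals.max(initial=0.0) <= _DEGENERATE_TOL),
    )


def reconstruct(result: EigenResult) -> np.ndarray:
    """Rank-k reconstruction U_left Σ Vᵀ of the sketched X (n×m)."""
    if result.left_vectors is None:
        raise ParameterError("result carries no left singular vectors")
    return result.left_vectors @ np.diag(result.singular_values) @ result.vectors.T


def svd_error_bound(m: int, n: int, k: int, q: int, sigma_next: float) -> float:
    """A-priori expected spectral-norm error of the rank-k randomized SVD.

    [1 + 4 sqrt(2 min(m,n)/(k-1))]^(1/(2q+1)) · σ_{k+1}; requires k >= 2
    (the constant diverges at k=1) and tends to σ_{k+1} as q grows.
    """
    if sigma_next < 0:
        raise ParameterError("sigma_next must be >= 0")
    if q < 0:
        raise ParameterError("q must be >= 0")
    if not (2 <= k <= 0.5 * min(m, n)):
        raise ParameterError(f"k={k} outside the validity range [2, 0.5*min(m,n)]")
    return (1.0 + 4.0 * np.sqrt(2.0 * min(m, n) / (k - 1))) ** (1.0 / (2 * q + 1)) * sigma_next


def power_method(
    apply, dim: int, iters: int = 100, seed: int | None = 0
) -> tuple[float, np.ndarray]:
    """Power iteration (Von Mises) for the leading eigenpair of a symmetric PSD operator.

    Runs exactly ``iters`` normalized iterations y ← A·y from a seeded
    Gaussian start and returns (Rayleigh quotient, unit vector).  A zero
    operator yields eigenvalue 0.0 (the start vector is returned).
    """
    if dim < 1:
        raise ParameterError("dim must be >= 1")
    if iters < 1:
        raise ParameterError("iters must be >= 1")
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(dim)
    y /= np.linalg.norm(y)
    for _ in range(iters):
        z = np.asarray(apply(y), dtype=np.float64)
        nz = np.linalg.norm(z)
        if nz == 0.0:
            return 0.0, y
        y = z / nz
    lam = float(y @ np.asarray(apply(y)))
    y, _ = fix_signs(y[:, None])
    return lam, y[:, 0]
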
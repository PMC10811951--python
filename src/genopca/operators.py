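"""Factored sparse operators X = a · v ⊙ (G ⊖ w).

Each factorable similarity matrix S can be written as S = X^T X where

    axis="row":     X_ij = a · v_j · (G_ij − w_j)     (v, w length m)
    axis="column":  X_ij = a · v_i · (G_ij − w_i)     (v, w length n)

i.e. X is the sparse genotype matrix G with a row- or column-wise
centering ⊖ and scaling ⊙ kept *symbolic*.  Centering would densify G,
so it is never applied; instead every product X·y and X^T·z separates
into a sparse product with G plus a rank-one correction:

    axis=column:  X y   = a (v ∘ (G y))  −  a (v ∘ w) (Σ_j y_j)
                  X^T z = a G^T (v ∘ z)  −  a ((v ∘ w)·z) 1_m

and analogously for axis=row.  Peak auxiliary storage is O(n + m) per
vector (O((n+m)·ell) for a block of ell vectors) beyond G itself.

Constructors are provided for the covariance matrix, the weighted
Jaccard matrix (with the minor-allele inversion baked into the stored
G), both GRM flavors and the approximate Jaccard matrix.  The exact
Jaccard matrix has *no* factorization in this family: its entrywise
union denominators depend on the column pair and cannot be absorbed
into the centering/scaling vectors (an abstract factor of a PSD J
exists but requires forming J itself, which is what this module is
built to avoid).

The operators count their applications (``matvec_calls`` /
``rmatvec_calls``, one per vector-or-block product) so the randomized
SVD's linear-complexity contract can be asserted by instrumentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import (
    CodingError,
    DegenerateInputError,
    ParameterError,
    ShapeError,
    SizeGuardError,
)
from .simdata import GenotypeMatrix
from . import similarity as ref

__all__ = [
    "FactoredOperator",
    "factor_covariance",
    "factor_weighted_jaccard",
    "factor_grm",
    "factor_approx_jaccard",
    "factor_for",
]


@dataclass
class FactoredOperator:
    """The tuple (a, v, w, axis, G) representing X = a·v⊙(G⊖w), never materialized."""

    a: float
    v: np.ndarray
    w: np.ndarray
    axis: str  # "row" | "column"
    G: GenotypeMatrix
    kind: str = "generic"
    matvec_calls: int = field(default=0, compare=False)
    rmatvec_calls: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.axis not in ("row", "column"):
            raise ParameterError(f"axis must be 'row' or 'column', got {self.axis!r}")
        if self.a <= 0:
            raise ParameterError("normalizer a must be positive")
        self.v = np.asarray(self.v, dtype=np.float64).ravel()
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        expect = self.G.m if self.axis == "row" else self.G.n
        if self.v.size != expect or self.w.size != expect:
            raise ShapeError(
                f"v/w must have length {expect} for axis={self.axis!r}; "
                f"got {self.v.size}/{self.w.size}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Shape (n, m) of the implied matrix X."""
        return self.G.values.shape

    def reset_counters(self) -> None:
        self.matvec_calls = 0
        self.rmatvec_calls = 0

    # -- products ----------------------------------------------------------

    def matvec(self, y: np.ndarray) -> np.ndarray:
        """X @ y for y of length m (or an m×l block), without densifying G."""
        y = np.asarray(y, dtype=np.float64)
        single = y.ndim == 1
        Y = y[:, None] if single else y
        if Y.shape[0] != self.G.m:
            raise ShapeError(f"matvec expects length {self.G.m}, got {Y.shape[0]}")
        Gm = self.G.values
        if self.axis == "row":
            # X = a (G − 1⊗w) diag(v):  X Y = a [G (v∘Y) − 1_n ((w∘v)ᵀ Y)]
            VY = self.v[:, None] * Y
            out = self.a * (Gm @ VY - np.outer(np.ones(self.G.n), (self.w * self.v) @ Y))
        else:
            # X = a diag(v) (G − w⊗1):  X Y = a [v∘(G Y) − (v∘w) (1ᵀ Y)]
            out = self.a * (self.v[:, None] * (Gm @ Y) - np.outer(self.v * self.w, Y.sum(axis=0)))
        self.matvec_calls += 1
        return out[:, 0] if single else out

    def rmatvec(self, z: np.ndarray) -> np.ndarray:
        """X.T @ z for z of length n (or an n×l block)."""
        z = np.asarray(z, dtype=np.float64)
        single = z.ndim == 1
        Z = z[:, None] if single else z
        if Z.shape[0] != self.G.n:
            raise ShapeError(f"rmatvec expects length {self.G.n}, got {Z.shape[0]}")
        Gm = self.G.values
        if self.axis == "row":
            # Xᵀ Z = a v ∘ [Gᵀ Z − w (1ᵀ Z)]
            out = self.a * self.v[:, None] * (Gm.T @ Z - np.outer(self.w, Z.sum(axis=0)))
        else:
            # Xᵀ Z = a [Gᵀ (v∘Z) − 1_m ((v∘w)ᵀ Z)]
            VZ = self.v[:, None] * Z
            out = self.a * (Gm.T @ VZ - np.outer(np.ones(self.G.m), (self.v * self.w) @ Z))
        self.rmatvec_calls += 1
        return out[:, 0] if single else out

    def materialize_dense(self, max_elements: int = 5_000_000) -> np.ndarray:
        """Literal dense evaluation of X (test oracle; guarded by size)."""
        n, m = self.shape
        if n * m > max_elements:
            raise SizeGuardError(
                f"refusing to densify a {n}×{m} operator (> {max_elements} elements)"
            )
        dense = self.G.toarray()
        if self.axis == "row":
            return self.a * (dense - self.w[None, :]) * self.v[None, :]
        return self.a * self.v[:, None] * (dense - self.w[:, None])

    def aslinearoperator(self) -> sparse.linalg.LinearOperator:
        """scipy LinearOperator view (for interoperability)."""
        n, m = self.shape
        return sparse.linalg.LinearOperator(
            (n, m), matvec=self.matvec, rmatvec=self.rmatvec, matmat=self.matvec
        )


# -- constructors ----------------------------------------------------------


def factor_covariance(G: GenotypeMatrix) -> FactoredOperator:
    """X with X^T X = covariance matrix: a=1/sqrt(n-1), v=1_m, w=column means."""
    if G.n < 2:
        raise DegenerateInputError("covariance needs n >= 2 loci")
    w = np.asarray(G.values.mean(axis=0)).ravel()
    return FactoredOperator(
        a=1.0 / np.sqrt(G.n - 1),
        v=np.ones(G.m),
        w=w,
        axis="row",
        G=G,
        kind="covariance",
    )


def factor_weighted_jaccard(
    G: GenotypeMatrix, count_basis: str = "loci"
) -> FactoredOperator:
    """X with X^T X = weighted Jaccard: a=1/sqrt(4n), v=sqrt(weights), w=0.

    The minor-allele inversion happens here; the (possibly inverted)
    genotype matrix is stored in the operator so the products stay
    generic.
    """
    Ginv, inter = ref.weighted_jaccard_weights(G, count_basis)
    return FactoredOperator(
        a=1.0 / np.sqrt(4.0 * G.n),
        v=np.sqrt(inter.weights),
        w=np.zeros(G.n),
        axis="column",
        G=Ginv,
        kind="weighted_jaccard",
    )


def factor_grm(G: GenotypeMatrix, robust: bool = True) -> FactoredOperator:
    """X with X^T X = GRM.  w = 2p; robust: a=1/sqrt(sum q), v=1_n;
    non-robust: a=1/sqrt(n), v=1/sqrt(q) (0 at monomorphic loci)."""
    inter = ref.grm_intermediates(G)
    if robust:
        if inter.ssum <= 0:
            raise DegenerateInputError("robust GRM undefined: all loci monomorphic")
        return FactoredOperator(
            a=1.0 / np.sqrt(inter.ssum),
            v=np.ones(G.n),
            w=2.0 * inter.p,
            axis="column",
            G=G,
            kind="grm_robust",
        )
    v = np.zeros_like(inter.qvec)
    nz = inter.qvec > 0
    v[nz] = 1.0 / np.sqrt(inter.qvec[nz])
    return FactoredOperator(
        a=1.0 / np.sqrt(G.n),
        v=v,
        w=2.0 * inter.p,
        axis="column",
        G=G,
        kind="grm_nonrobust",
    )


def factor_approx_jaccard(G: GenotypeMatrix) -> FactoredOperator:
    """X with X^T X = approximate Jaccard: a=1/sqrt(2 max(s)), v=1_m, w=0."""
    if G.coding != "binary":
        raise CodingError("approximate Jaccard requires a binary genotype matrix")
    s = np.asarray(G.values.sum(axis=0)).ravel()
    smax = s.max(initial=0.0)
    if smax <= 0:
        raise DegenerateInputError("approximate Jaccard undefined for an all-zero matrix")
    return FactoredOperator(
        a=1.0 / np.sqrt(2.0 * smax),
        v=np.ones(G.m),
        w=np.zeros(G.m),
        axis="row",
        G=G,
        kind="approx_jaccard",
    )


_FACTORIES = {
    "covariance": factor_covariance,
    "weighted_jaccard": factor_weighted_jaccard,
    "grm_robust": lambda G: factor_grm(G, robust=True),
    "grm_nonrobust": lambda G: factor_grm(G, robust=False),
    "approx_jaccard": factor_approx_jaccard,
}


def factor_for(kind: str, G: GenotypeMatrix, **kwargs) -> FactoredOperator:
    """Dispatch a factored operator by similarity kind.

    ``kind='jaccard'`` is rejected: the exact Jaccard matrix admits no
    factorization in the centered/scaled sparse operator family.
    """
    if kind == "jaccard":
        raise ParameterError(
            "the exact Jaccard matrix admits no X^T X factorization in the "
            "sparse operator family (its union denominators vary per column "
            "pair); use 'approx_jaccard' or the dense path"
        )
    try:
        factory = _FACTORIES[kind]
    except KeyError:
        raise ParameterError(f"unknown similarity kind {kind!r}") from None
    return factory(G, **kwargs) if kwargs else factory(G)
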
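"""Dense reference implementations of the five similarity matrices.

These are the literal, loop-free definitions of the covariance matrix,
Jaccard matrix, approximate Jaccard matrix, weighted Jaccard matrix and
the genomic relationship matrix (robust and non-robust).  They serve as
correctness oracles for the factored-operator fast path and as the CLI's
dense fallback; they densify the genotype matrix and are therefore only
meant for inputs of moderate size.

Conventions for degenerate inputs (the definitions are silent on them):

* Jaccard 0/0 entries — two all-zero columns, or the diagonal entry of
  an all-zero column — are set to 0: no shared variants is no evidence
  of similarity, and NaN must not propagate.
* Weighted-Jaccard loci whose (post-inversion) row sum is 0 or 1 carry
  no pairwise-sharing information (totalPairs = 0) and get weight 0.
* Non-robust GRM loci that are monomorphic (2p(1-p) = 0) would get an
  infinite weight; they are given weight 0 instead, mirroring the
  robust flavor where such loci contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .errors import CodingError, DegenerateInputError, ParameterError
from .simdata import GenotypeMatrix

__all__ = [
    "SimilarityMatrix",
    "WeightedJaccardIntermediates",
    "GrmIntermediates",
    "JaccardCounts",
    "covariance_matrix",
    "jaccard_matrix",
    "approx_jaccard_matrix",
    "jaccard_counts",
    "weighted_jaccard_matrix",
    "grm",
]

KINDS = (
    "covariance",
    "jaccard",
    "approx_jaccard",
    "weighted_jaccard",
    "grm_robust",
    "grm_nonrobust",
)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Dense symmetric m×m similarity matrix with a kind tag."""

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown similarity kind {self.kind!r}")
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("similarity matrix must be square")

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightedJaccardIntermediates:
    """Intermediate quantities of the weighted-Jaccard computation."""

    num_alleles: int
    sum_variants: np.ndarray      # original row sums, length n
    row_sums: np.ndarray          # row sums after minor-allele inversion
    total_pairs: np.ndarray       # s(s-1)/2 on the inverted matrix
    weights: np.ndarray           # per-locus rarity weights, 0 where total_pairs = 0
    inverted_rows: np.ndarray     # indices of rows that were bit-inverted


@dataclass(frozen=True)
class GrmIntermediates:
    """Per-locus quantities entering the GRM."""

    p: np.ndarray     # half row means
    qvec: np.ndarray  # 2 p (1 - p)
    ssum: float       # sum of qvec


@dataclass(frozen=True)
class JaccardCounts:
    """Pairwise intersection/union counts of binary variant profiles."""

    A: np.ndarray        # m×m intersection counts, = G^T G for binary G
    O: np.ndarray        # m×m union counts, O_ij = s_i + s_j - A_ij
    colsums: np.ndarray  # length-m column sums s


def _require_binary(G: GenotypeMatrix, op: str) -> None:
    if G.coding != "binary":
        raise CodingError(f"{op} requires a binary genotype matrix, got {G.coding!r}")


def covariance_matrix(G: GenotypeMatrix) -> SimilarityMatrix:
    """Sample covariance of individuals: (1/(n-1)) C^T C with columns centered.

    Each column (individual) has its mean across loci subtracted; the
    unbiased 1/(n-1) normalizer requires at least two loci.
    """
    if G.n < 2:
        raise DegenerateInputError("covariance needs n >= 2 loci")
    dense = G.toarray()
    centered = dense - dense.mean(axis=0, keepdims=True)
    vals = centered.T @ centered / (G.n - 1)
    return SimilarityMatrix(vals, "covariance")


def jaccard_counts(G: GenotypeMatrix) -> JaccardCounts:
    """Intersection (and) and union (or) counts over column pairs."""
    _require_binary(G, "jaccard")
    dense = G.toarray()
    A = dense.T @ dense
    s = dense.sum(axis=0)
    O = s[:, None] + s[None, :] - A
    return JaccardCounts(A=A, O=O, colsums=s)


def jaccard_matrix(G: GenotypeMatrix) -> SimilarityMatrix:
    """Exact Jaccard similarity J = A/O with 0/0 entries defined as 0.

    The intersection counts A = GᵀG are a Gram matrix, but the pairwise
    union denominators O_ij vary per column pair and cannot be absorbed
    into any per-row/per-column scaling of G — J has no factorization in
    the sparse operator family and hence no fast randomized-SVD path.
    (On binary input J itself is a positive-definite kernel Gram matrix;
    applied to non-binary input the same formula loses even that.)
    """
    counts = jaccard_counts(G)
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(counts.O > 0, counts.A / np.where(counts.O > 0, counts.O, 1.0), 0.0)
    return SimilarityMatrix(J, "jaccard")


def approx_jaccard_matrix(G: GenotypeMatrix) -> SimilarityMatrix:
    """Approximate Jaccard Ĵ = A / (2 max(s)), a PSD Gram surrogate for J.

    2·max(s) is the largest union count any column pair could attain, so
    every entry of Ĵ is a conservative underestimate of the matching
    entry of J (never overestimating the similarity of two individuals),
    while Ĵ ∝ G^T G is positive semi-definite and factorable.
    """
    counts = jaccard_counts(G)
    smax = counts.colsums.max(initial=0.0)
    if smax <= 0:
        raise DegenerateInputError("approximate Jaccard undefined for an all-zero matrix")
    return SimilarityMatrix(counts.A / (2.0 * smax), "approx_jaccard")


def invert_minor_alleles(
    G: GenotypeMatrix, count_basis: str = "loci"
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Flip binary rows whose sum exceeds the count-basis threshold.

    Returns (possibly inverted matrix, original row sums, inverted row
    indices).  ``count_basis='loci'`` uses the locus count n as the
    threshold (the literal published procedure); ``'individuals'`` uses
    the column count m, which is the dimensionally natural reading since
    each row has m entries.  With n >= m (the usual genomic regime) the
    literal threshold never triggers.
    """
    _require_binary(G, "minor-allele inversion")
    if count_basis not in ("loci", "individuals"):
        raise ParameterError(f"count_basis must be 'loci' or 'individuals', got {count_basis!r}")
    threshold = G.n if count_basis == "loci" else G.m
    dense = G.toarray()
    sum_variants = dense.sum(axis=1)
    inverted = np.flatnonzero(sum_variants > threshold)
    if inverted.size:
        dense = dense.copy()
        dense[inverted] = 1.0 - dense[inverted]
    return (
        GenotypeMatrix(sparse.csr_matrix(dense), coding="binary"),
        sum_variants,
        inverted,
    )


def weighted_jaccard_weights(
    G: GenotypeMatrix, count_basis: str = "loci"
) -> tuple[GenotypeMatrix, WeightedJaccardIntermediates]:
    """Minor-allele inversion plus per-locus rarity weights.

    numAlleles = 2·(count basis); totalPairs_i = s_i(s_i - 1)/2 with s
    the row sums *after* inversion; weight_i = numAlleles(numAlleles-1)
    / totalPairs_i, or 0 where totalPairs_i = 0.  Rare loci (small s_i)
    thus receive large weights.
    """
    Ginv, sum_variants, inverted = invert_minor_alleles(G, count_basis)
    basis = G.n if count_basis == "loci" else G.m
    num_alleles = 2 * basis
    s = np.asarray(Ginv.values.sum(axis=1)).ravel()
    total_pairs = s * (s - 1) / 2.0
    weights = np.zeros_like(total_pairs)
    nz = total_pairs > 0
    weights[nz] = num_alleles * (num_alleles - 1) / total_pairs[nz]
    inter = WeightedJaccardIntermediates(
        num_alleles=num_alleles,
        sum_variants=sum_variants,
        row_sums=s,
        total_pairs=total_pairs,
        weights=weights,
        inverted_rows=inverted,
    )
    return Ginv, inter


def weighted_jaccard_matrix(
    G: GenotypeMatrix, count_basis: str = "loci"
) -> tuple[SimilarityMatrix, WeightedJaccardIntermediates]:
    """Weighted Jaccard matrix (1/(4n)) G^T diag(weights) G on the inverted matrix."""
    Ginv, inter = weighted_jaccard_weights(G, count_basis)
    dense = Ginv.toarray()
    vals = (dense * inter.weights[:, None]).T @ dense / (4.0 * G.n)
    return SimilarityMatrix(vals, "weighted_jaccard"), inter


def grm_intermediates(G: GenotypeMatrix) -> GrmIntermediates:
    p = np.asarray(G.values.mean(axis=1)).ravel() / 2.0
    qvec = 2.0 * p * (1.0 - p)
    return GrmIntermediates(p=p, qvec=qvec, ssum=float(qvec.sum()))


def grm(
    G: GenotypeMatrix, robust: bool = True
) -> tuple[SimilarityMatrix, GrmIntermediates]:
    """Genomic relationship matrix from allele-frequency-centered genotypes.

    With p the half row means and q = 2p(1-p), columns are centered by
    2p; the robust flavor normalizes globally by sum(q), the non-robust
    flavor weights each locus by 1/q_i (0 for monomorphic loci) and
    divides by n.
    """
    inter = grm_intermediates(G)
    centered = G.toarray() - 2.0 * inter.p[:, None]
    if robust:
        if inter.ssum <= 0:
            raise DegenerateInputError("robust GRM undefined: all loci monomorphic (sum q = 0)")
        vals = centered.T @ centered / inter.ssum
        kind = "grm_robust"
    else:
        w = np.zeros_like(inter.qvec)
        nz = inter.qvec > 0
        w[nz] = 1.0 / inter.qvec[nz]
        vals = (centered * w[:, None]).T @ centered / G.n
        kind = "grm_nonrobust"
    return SimilarityMatrix(vals, kind), inter
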
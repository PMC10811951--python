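"""Synthetic genotype matrices.

The package operates on a loci-by-individuals genotype matrix
``G`` (n rows = variants/loci, m columns = individuals/samples), stored
sparse.  Two codings are supported:

``binary``
    entries in {0, 1}; 1 marks presence of (at least one) minor allele.
    This is the input of the Jaccard-family similarity matrices.
``dosage012``
    entries in {0, 1, 2}; the count of alternate alleles.  This is the
    input of the covariance matrix and the genomic relationship matrix.

The generators in this module provide the simulation settings used to
exercise every downstream computation: i.i.d. Bernoulli sparse binary
matrices with a nonzero proportion ``pi``, binomial(2, p) dosage
matrices with per-locus allele frequencies, and a stratified-population
dosage generator (Balding–Nichols style two-level frequency model) for
demonstrating population structure in the leading principal components.

All randomness is driven by an explicit integer seed per call; there is
no global RNG state, so every matrix is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import CodingError, ParameterError

__all__ = [
    "GenotypeMatrix",
    "SimConfig",
    "generate_binary",
    "generate_dosage",
    "generate_stratified",
]

_CODINGS = ("binary", "dosage012")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Sparse n×m loci-by-individuals genotype matrix with a coding tag.

    Parameters
    ----------
    values
        Sparse matrix (stored CSR, dtype float64) whose entries are
        non-negative integers from the coding's value set.
    coding
        Either ``"binary"`` ({0,1}) or ``"dosage012"`` ({0,1,2}).
    """

    values: sparse.csr_matrix
    coding: str = "binary"

    def __post_init__(self) -> None:
        if self.coding not in _CODINGS:
            raise CodingError(f"unknown coding {self.coding!r}; expected one of {_CODINGS}")
        mat = sparse.csr_matrix(self.values, dtype=np.float64)
        object.__setattr__(self, "values", mat)
        if mat.shape[0] < 1 or mat.shape[1] < 1:
            raise ParameterError("genotype matrix must have at least one row and column")
        allowed = {0.0, 1.0} if self.coding == "binary" else {0.0, 1.0, 2.0}
        if mat.nnz and not set(np.unique(mat.data)).issubset(allowed):
            raise CodingError(
                f"values outside {sorted(allowed)} for coding {self.coding!r}"
            )

    @property
    def n(self) -> int:
        """Number of loci (rows)."""
        return self.values.shape[0]

    @property
    def m(self) -> int:
        """Number of individuals (columns)."""
        return self.values.shape[1]

    def toarray(self) -> np.ndarray:
        """Dense copy (for oracles and small inputs only)."""
        return self.values.toarray()


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the i.i.d. Bernoulli binary simulation.

    ``pi`` is the expected proportion of entries equal to one (the
    nonzero-allele proportion); the default 0.1 is the sparsity level
    used throughout the package's own accuracy experiments.
    """

    n: int
    m: int
    pi: float = 0.1
    seed: int = 0
    coding: str = "binary"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi <= 1.0):
            raise ParameterError(f"pi must lie in [0, 1]; got {self.pi}")
        if self.n < 1 or self.m < 1:
            raise ParameterError("n and m must be positive")


def generate_binary(config: SimConfig) -> GenotypeMatrix:
    """Draw an n×m binary matrix with i.i.d. Bernoulli(pi) entries.

    No row or column structure is imposed; identical configs produce
    bit-identical matrices.
    """
    if config.coding != "binary":
        raise ParameterError("generate_binary requires coding='binary'")
    rng = np.random.default_rng(config.seed)
    dense = (rng.random((config.n, config.m)) < config.pi).astype(np.float64)
    return GenotypeMatrix(sparse.csr_matrix(dense), coding="binary")


def generate_dosage(
    n: int, m: int, maf_low: float = 0.05, maf_high: float = 0.5, seed: int = 0
) -> GenotypeMatrix:
    """Draw an n×m dosage matrix with binomial(2, p_i) entries.

    Each locus gets an allele frequency ``p_i`` uniform in
    ``[maf_low, maf_high]``; entries in row i are i.i.d. binomial(2, p_i)
    alternate-allele counts.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ParameterError(
            f"need 0 < maf_low <= maf_high <= 0.5; got ({maf_low}, {maf_high})"
        )
    if n < 1 or m < 1:
        raise ParameterError("n and m must be positive")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n)
    dense = rng.binomial(2, p[:, None], size=(n, m)).astype(np.float64)
    return GenotypeMatrix(sparse.csr_matrix(dense), coding="dosage012")


def generate_stratified(
    n: int,
    m_per_pop: int,
    n_pops: int = 2,
    divergence: float = 0.1,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw a dosage matrix for ``n_pops`` diverged populations.

    A two-level frequency model: ancestral allele frequencies are
    uniform in [0.05, 0.5]; each population's frequency at a locus is a
    Balding–Nichols beta draw around the ancestral value with fixation
    index F = ``divergence`` (``divergence=0`` collapses to a single
    panmictic population).  Individuals then receive binomial(2, p_pop)
    dosages.  Returns the matrix and an integer population label per
    column.  This is a synthetic stand-in for structured cohort data,
    intended for demonstrating stratification in the leading PCs.
    """
    if n_pops < 1:
        raise ParameterError("n_pops must be >= 1")
    if divergence < 0:
        raise ParameterError("divergence must be >= 0")
    if n < 1 or m_per_pop < 1:
        raise ParameterError("n and m_per_pop must be positive")
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.5, size=n)
    cols = []
    labels = np.repeat(np.arange(n_pops), m_per_pop)
    for _ in range(n_pops):
        if divergence > 0:
            f = divergence
            alpha = ancestral * (1 - f) / f
            beta = (1 - ancestral) * (1 - f) / f
            p_pop = rng.beta(alpha, beta)
        else:
            p_pop = ancestral
        cols.append(rng.binomial(2, p_pop[:, None], size=(n, m_per_pop)))
    dense = np.concatenate(cols, axis=1).astype(np.float64)
    return GenotypeMatrix(sparse.csr_matrix(dense), coding="dosage012"), labels
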
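# Methods

## Similarity matrices and their factored forms

All computations start from a loci×individuals genotype matrix
G ∈ R^{n×m}. Five similarity matrices are supported through one
representation, X = a·v⊙(G⊖w) with S = XᵀX, where ⊖/⊙ denote row- or
column-wise subtraction/multiplication of a vector kept symbolic:

* **Covariance** (dosage or binary input): columns are centered by their
  own means (w = μ_c(G), length m) and S = (1/(n−1))CᵀC. Note this
  centers each *individual's* profile, not each locus: a shared
  locus-frequency profile across individuals is **not** removed, so on
  structured cohorts the leading covariance PC is typically the shared
  frequency axis and the population split appears from PC2 on.
* **GRM**, robust and non-robust (dosage input): rows are centered by
  twice the per-locus allele frequency (w = 2p), which removes exactly
  that shared axis — this is why the GRM is the stratification PCA of
  choice. The robust flavor divides by Σ 2p(1−p) globally; the
  non-robust flavor weights each locus by 1/(2p(1−p)) and divides by n.
  Monomorphic loci (2p(1−p) = 0) get weight 0 in the non-robust flavor
  (the robust flavor ignores them implicitly); a fully monomorphic
  matrix leaves the robust GRM undefined and raises.
* **Weighted Jaccard** (binary input): after minor-allele inversion
  (rows whose sum exceeds the count basis are bit-flipped), each locus
  gets rarity weight numAlleles(numAlleles−1)/totalPairs with
  totalPairs = s(s−1)/2 computed from the *post-inversion* row sums;
  loci with row sum 0 or 1 carry no pairwise-sharing information and
  get weight 0. S = (1/(4n))Gᵀdiag(weights)G. The published procedure
  sets numAlleles = 2n and the inversion threshold to the locus count
  n, although each row has m entries; both readings are implemented
  (`count_basis = "loci"` — the literal default — or `"individuals"`).
  In the usual regime n ≫ m the literal threshold simply never fires.
* **Approximate Jaccard** (binary input): Ĵ = GᵀG/(2·max s). The
  denominator is the largest union count any column pair could attain,
  so Ĵ underestimates J entrywise wherever a union exists, and Ĵ is a
  scaled Gram matrix, hence PSD and factorable.

The **exact Jaccard matrix** J = A/O is deliberately not factored. The
obstruction is structural: O_ij = s_i + s_j − A_ij varies per column
pair and cannot be absorbed into per-row or per-column scaling vectors.
It is *not* indefiniteness: the Jaccard/Tanimoto index is a known
positive-definite kernel, and exhaustive enumeration of all binary
matrices up to ~1.1M instances (shapes 2×4 … 3×5) confirms the smallest
eigenvalue is numerical zero. (Applying the same A/O formula to 0/1/2
dosage input does produce negative eigenvalues, which is why the
Jaccard-family functions enforce binary coding.) An abstract Cholesky
factor of a PSD J of course exists, but obtaining it requires forming J
— the very O(nm²) step this package exists to avoid. Degenerate 0/0
Jaccard entries (two all-zero columns, or the diagonal of an all-zero
column) are defined as 0: no shared variants is no evidence of
similarity, and NaNs must not propagate.

## Sparse products and the randomized eigensolver

Centering G would densify it, so X is never materialized. Every product
separates into a sparse product with G plus a rank-one correction, e.g.
for the column axis X·y = a(v∘(Gy)) − a(v∘w)(Σy): auxiliary storage is
O(n+m) per vector and the cost is O(nnz(G)) per application. The
operators count their applications so complexity claims are assertable
by instrumentation rather than wall-clock.

The eigensolver is a Gaussian-sketch randomized SVD with power
iteration. Because the wanted eigenvectors of S = XᵀX have length m,
the sketch runs on Xᵀ: Ω ∈ R^{n×2k}, Y = (XᵀX)^q XᵀΩ, reduced QR gives
Q ∈ R^{m×2k}, B = QᵀXᵀ ∈ R^{2k×n} gets a small exact SVD truncated to
k, and U = QŨ_k are the PCs with eigenvalues the squared singular
values. The sketch width is fixed at 2k; the default power exponent is
q = 2k (user-overridable — larger q buys accuracy at linear extra
cost); one RNG stream per call is derived from an explicit integer
seed, and the dense-input and operator-input paths consume the stream
identically, so they agree to floating-point reassociation under a
shared seed. Each returned eigenvector is flipped so its
largest-magnitude entry is positive (eigenvectors are defined up to
sign; reproducibility requires a convention). k = 1 sits outside the
validity range of the a-priori bound (its constant diverges at k = 1)
and is allowed only behind an explicit flag. An all-zero operator
yields zero eigenvalues with a `degenerate` flag rather than an error.
Per-iteration re-orthonormalization is not performed: at the q values
used here (≤ ~20) the power products stay well-conditioned because QR
happens once on the accumulated sketch, and the dense/fast
equality contract requires both paths to do exactly the same
arithmetic.

Accuracy in q is governed by
E‖X − UΣVᵀ‖₂ ≤ [1 + 4√(2 min(m,n)/(k−1))]^{1/(2q+1)} σ_{k+1}; the bound
is on the expectation over the Gaussian sketch, so the test suite
checks it in the mean over 100 sketches. A power-method baseline (100
fixed normalized iterations, Rayleigh quotient) is provided for the
leading eigenpair.

## Eigenvector error bounds for the Jaccard approximation

For symmetric J, Ĵ with sorted spectra, the Davis–Kahan sin(θ) theorem
gives the chain

    min_ε ‖u_i − ε û_i‖₂ ≤ √2|sin ∠(u_i, û_i)| ≤ 2√2 ‖J−Ĵ‖ / gap.

The operator norm may be relaxed to the Frobenius norm (the default in
reports — it only loosens the bound). The gap can be estimated three
ways: dense eigensolver (oracle-grade), power method with sequential
deflation (100 iterations per stage), or Gershgorin disc arithmetic for
a fully a-priori bound. The Gershgorin route merges overlapping discs
into clusters — a cluster of c discs contains exactly c eigenvalues —
and returns lower-edge(λ_i's cluster) − upper-edge(λ_{i+1}'s cluster),
a valid lower bound on the true gap that never makes the bound
spuriously tight; when the two eigenvalues share a cluster the gap
estimate is non-positive and the bound is reported as vacuous (infinite
with a flag) rather than raised, since degenerate spectra are
legitimate inputs.

Reports for higher-order eigenvectors default to the *leading* gap in
the matrix bound — the bound then depends only on J and Ĵ, so it is
identical across orders, matching its published use. The consecutive
gap max(λ_i−λ_{i+1}, λ̂_i−λ̂_{i+1}), the natural order-i analogue of
the first-order theorem, is available via `higher_order_gaps=True`; it
is an extrapolation, which is why it sits behind an explicit switch.
Measured distances and both bounds in `jaccard_bound_report` use dense
oracle-grade eigenpairs, and the report is size-guarded since it must
form J densely.

## Synthetic data

The generators provide exactly the statistical structure the accuracy
experiments need, not realistic genomes:

* `generate_binary(n, m, pi, seed)`: i.i.d. Bernoulli(π) entries,
  default π = 0.1 — the sparsity used throughout the accuracy and
  bound-verification experiments. No row/column structure, no LD.
* `generate_dosage`: per-locus allele frequency uniform in
  [maf_low, maf_high] (default [0.05, 0.5]), entries binomial(2, p_i).
* `generate_stratified`: two-level Balding–Nichols model — ancestral
  frequencies uniform in [0.05, 0.5], per-population frequencies beta
  draws with fixation index F = divergence (default 0.1, a
  continental-scale value), dosages binomial(2, p_pop). It emulates
  discrete diverged populations only: no admixture, no LD, no
  relatedness, no missingness. Passing tests on these fixtures
  demonstrates algebraic and numerical correctness of the method, not
  robustness to real-data artifacts.

All generators take one explicit integer seed and are bit-reproducible;
all-zero rows/columns are *not* excluded (downstream code must and does
handle them).

## Problem sizes and numerical choices

The validation suites run at desk scale, chosen to exercise every claim
while keeping the dense oracles cheap: decomposition exactness at
200×50 over 25 seeds (tolerance 1e−10 entrywise; the decompositions are
algebraically exact, so the tolerance only absorbs floating-point
error), randomized-vs-dense agreement at 500×100 with k=2, q=10, the
error-plateau sweep at n ∈ {100,…,1600} with m=100 (mean over 5 seeds
per size), the bound chain at 1000×100 over 20 seeds plus a sparsity
sweep π ∈ {0.1,…,0.9}, and the a-priori SVD bound at 60×30 over 100
sketches. The |cos| ≥ 0.999 agreement contract is asserted conditional
on a relative eigengap ≥ 0.05: below that, no power-iteration scheme at
q=10 can separate the eigenvectors, and unstructured Bernoulli matrices
(Marchenko–Pastur edge, relative gaps ~0.01) sit squarely in that
regime — the structured-cohort fixture is what makes the assertion
non-vacuous.

Dense materialization and the dense Jaccard oracle are guarded at 5e6
elements. Symmetry of reference matrices holds to 1e−12; PSD assertions
allow −1e−10 (relative to the spectral norm) for eigensolver round-off.

## Known limitations

* No LD pruning, rare-variant filtering, or PLINK-format input; VCF
  conversion is minimal (biallelic GT only, missing → 0 with a logged
  count).
* The exact-Jaccard PCA is dense-only by design.
* Sketch width is fixed at 2k; no adaptive rank selection or block
  Krylov variants.
* The higher-order consecutive-gap bound is an extrapolation of the
  first-order theorem, not a proved statement.
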
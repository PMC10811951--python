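import itertools

import numpy as np
import pytest

from genopca.errors import CodingError, DegenerateInputError
from genopca.similarity import (
    approx_jaccard_matrix,
    covariance_matrix,
    grm,
    jaccard_counts,
    jaccard_matrix,
    weighted_jaccard_matrix,
)
from genopca.simdata import generate_dosage

from conftest import binary_matrix, dosage_matrix, random_binary

SYM_TOL = 1e-12


def jaccard_by_enumeration(dense):
    """Independent oracle: pairwise and/or counts by explicit column loops."""
    m = dense.shape[1]
    J = np.zeros((m, m))
    for i, j in itertools.product(range(m), range(m)):
        ci, cj = dense[:, i] > 0, dense[:, j] > 0
        union = np.sum(ci | cj)
        J[i, j] = np.sum(ci & cj) / union if union else 0.0
    return J


class TestCovariance:
    def test_hand_example(self):
        S = covariance_matrix(binary_matrix([[1, 0], [0, 1]]))
        np.testing.assert_allclose(S.values, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-15)

    def test_constant_matrix_maps_to_zero(self):
        S = covariance_matrix(binary_matrix(np.ones((4, 3))))
        assert np.all(S.values == 0)

    def test_matches_numpy_cov_oracle(self):
        G = generate_dosage(5, 4, seed=3)
        S = covariance_matrix(G)
        np.testing.assert_allclose(S.values, np.cov(G.toarray().T, bias=False), atol=1e-12)

    def test_single_locus_rejected(self):
        with pytest.raises(DegenerateInputError):
            covariance_matrix(binary_matrix([[1, 0]]))


class TestJaccard:
    def test_hand_pair(self):
        # columns (1,1,0) and (1,0,1): |and|=1, |or|=3
        J = jaccard_matrix(binary_matrix([[1, 1], [1, 0], [0, 1]]))
        assert J.values[0, 1] == pytest.approx(1 / 3)

    def test_identical_and_disjoint_columns(self):
        J = jaccard_matrix(binary_matrix([[1, 1, 0], [1, 1, 0], [0, 0, 1]]))
        assert J.values[0, 1] == 1.0
        assert J.values[0, 2] == 0.0

    def test_zero_column_rule(self):
        # 0/0 entries (all-zero columns) are defined as 0, diagonal included
        J = jaccard_matrix(binary_matrix([[1, 0], [1, 0]]))
        assert J.values[1, 1] == 0.0 and J.values[0, 1] == 0.0
        assert J.values[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        G = random_binary(12, 7, pi=0.3, seed=seed)
        np.testing.assert_allclose(
            jaccard_matrix(G).values, jaccard_by_enumeration(G.toarray()), atol=1e-14
        )

    def test_intersection_counts_equal_gram_product(self):
        # A = G^T G: the logical-and counts are exactly the Gram matrix
        for seed in range(5):
            G = random_binary(15, 6, pi=0.4, seed=seed)
            dense = G.toarray()
            counts = jaccard_counts(G)
            np.testing.assert_array_equal(counts.A, dense.T @ dense)
            np.testing.assert_array_equal(
                counts.O, counts.colsums[:, None] + counts.colsums[None, :] - counts.A
            )

    def test_rejects_dosage(self):
        with pytest.raises(CodingError):
            jaccard_matrix(dosage_matrix([[2, 0], [0, 1]]))

    def test_jaccard_is_a_positive_definite_kernel(self):
        # the Jaccard/Tanimoto index is a positive-definite kernel, so its
        # Gram matrix over binary columns is PSD on every instance a seeded
        # search can produce; what blocks the fast path is not indefiniteness
        # but the absence of any factorization of J in the centered/scaled
        # sparse operator family (the pairwise union denominators cannot be
        # absorbed into per-row or per-column vectors)
        for seed in range(50):
            G = random_binary(8, 6, pi=0.4, seed=seed)
            lam = np.linalg.eigvalsh(jaccard_matrix(G).values)
            assert lam.min() >= -1e-10

    def test_jaccard_formula_on_dosage_input_can_be_indefinite(self):
        # applying A/O naively to 0/1/2 dosages (outside this package's
        # binary contract) does produce negative eigenvalues — the practical
        # reason the Jaccard-family matrices here insist on binary coding
        found = False
        for seed in range(200):
            rng = np.random.default_rng(seed)
            dense = rng.binomial(2, 0.3, size=(10, 6)).astype(float)
            A = dense.T @ dense
            s = dense.sum(axis=0)
            O = s[:, None] + s[None, :] - A
            with np.errstate(invalid="ignore", divide="ignore"):
                J = np.where(O > 0, A / np.where(O > 0, O, 1.0), 0.0)
            if np.linalg.eigvalsh(J).min() < -1e-9:
                found = True
                break
        assert found


class TestApproxJaccard:
    def test_hand_example(self, toy_columns_ajc):
        # s=(2,2,1), so Jhat = A/4 and Jhat_12 = 1/4 <= J_12 = 1/3
        Jhat = approx_jaccard_matrix(toy_columns_ajc)
        J = jaccard_matrix(toy_columns_ajc)
        assert Jhat.values[0, 1] == pytest.approx(0.25)
        assert Jhat.values[0, 1] <= J.values[0, 1]

    def test_single_one_columns(self):
        # two identical single-one columns: Jhat_12 = 1/2 while J_12 = 1
        G = binary_matrix([[1, 1]])
        assert approx_jaccard_matrix(G).values[0, 1] == pytest.approx(0.5)
        assert jaccard_matrix(G).values[0, 1] == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_never_overestimates_and_psd(self, seed):
        G = random_binary(40, 15, pi=0.2, seed=seed)
        J = jaccard_matrix(G).values
        Jhat = approx_jaccard_matrix(G).values
        O = jaccard_counts(G).O
        assert np.all(Jhat[O > 0] <= J[O > 0] + 1e-12)
        norm = np.linalg.norm(Jhat, 2)
        assert np.linalg.eigvalsh(Jhat).min() >= -1e-10 * max(norm, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            approx_jaccard_matrix(binary_matrix(np.zeros((3, 3))))


class TestWeightedJaccard:
    def test_hand_example(self, toy_binary_3x3):
        S, inter = weighted_jaccard_matrix(toy_binary_3x3)
        np.testing.assert_allclose(inter.weights, [30, 30, 30])
        np.testing.assert_allclose(np.diag(S.values), [5, 5, 5])
        off = S.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 2.5)
        assert inter.num_alleles == 6
        assert inter.inverted_rows.size == 0

    def test_singleton_row_gets_zero_weight(self):
        S, inter = weighted_jaccard_matrix(binary_matrix([[1, 0, 0], [1, 1, 0], [0, 1, 1]]))
        assert inter.weights[0] == 0.0
        assert np.all(np.isfinite(S.values))

    def test_heavy_row_inverted_to_zero(self):
        # row (1,1,1,1) in a 3x4 matrix: row sum 4 > n=3, so it is inverted
        # to all zeros and ends up with weight 0
        G = binary_matrix([[1, 1, 1, 1], [1, 0, 0, 0], [0, 1, 0, 0]])
        _, inter = weighted_jaccard_matrix(G, count_basis="loci")
        assert list(inter.inverted_rows) == [0]
        assert inter.row_sums[0] == 0.0
        assert inter.weights[0] == 0.0

    def test_individuals_count_basis(self):
        # with the column-count basis, a row of 3 ones among m=4 individuals
        # is not inverted (3 <= 4) and numAlleles = 2m = 8
        G = binary_matrix([[1, 1, 1, 0], [1, 0, 0, 0], [0, 1, 0, 0]])
        _, inter = weighted_jaccard_matrix(G, count_basis="individuals")
        assert inter.num_alleles == 8
        assert inter.inverted_rows.size == 0

    def test_rejects_dosage(self):
        with pytest.raises(CodingError):
            weighted_jaccard_matrix(dosage_matrix([[2, 0], [0, 1]]))


class TestGrm:
    def test_hand_example_both_flavors(self, toy_dosage_2x2):
        expected = [[1.0, -1.0], [-1.0, 1.0]]
        np.testing.assert_allclose(grm(toy_dosage_2x2, robust=True)[0].values, expected, atol=1e-14)
        np.testing.assert_allclose(grm(toy_dosage_2x2, robust=False)[0].values, expected, atol=1e-14)

    def test_zero_row_contributes_nothing(self):
        base = dosage_matrix([[0, 2], [1, 1]])
        padded = dosage_matrix([[0, 2], [1, 1], [0, 0]])
        for robust in (True, False):
            Sb = grm(base, robust)[0].values
            Sp = grm(padded, robust)[0].values
            # robust: same ssum, identical; non-robust: only the 1/n changes
            scale = 1.0 if robust else 3 / 2
            np.testing.assert_allclose(Sp * scale, Sb, atol=1e-12)

    def test_all_monomorphic_robust_rejected(self):
        with pytest.raises(DegenerateInputError):
            grm(dosage_matrix([[2, 2], [0, 0]]), robust=True)

    def test_intermediates(self, toy_dosage_2x2):
        _, inter = grm(toy_dosage_2x2, robust=True)
        np.testing.assert_allclose(inter.p, [0.5, 0.5])
        np.testing.assert_allclose(inter.qvec, [0.5, 0.5])
        assert inter.ssum == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_symmetry_and_psd_of_factorable_matrices(seed):
    Gb = random_binary(30, 12, pi=0.3, seed=seed)
    Gd = generate_dosage(30, 12, seed=seed)
    mats = [
        covariance_matrix(Gd).values,
        weighted_jaccard_matrix(Gb)[0].values,
        grm(Gd, robust=True)[0].values,
        grm(Gd, robust=False)[0].values,
        approx_jaccard_matrix(Gb).values,
        jaccard_matrix(Gb).values,
    ]
    for M in mats:
        assert np.abs(M - M.T).max() < SYM_TOL
    for M in mats[:-1]:  # all but the exact Jaccard are PSD
        norm = max(np.linalg.norm(M, 2), 1.0)
        assert np.linalg.eigvalsh(M).min() >= -1e-10 * norm
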
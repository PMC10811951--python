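import numpy as np
import pytest
from scipy import sparse

from genopca.simdata import GenotypeMatrix, SimConfig, generate_binary, generate_dosage


def binary_matrix(arr) -> GenotypeMatrix:
    return GenotypeMatrix(sparse.csr_matrix(np.asarray(arr, dtype=float)), coding="binary")


def dosage_matrix(arr) -> GenotypeMatrix:
    return GenotypeMatrix(sparse.csr_matrix(np.asarray(arr, dtype=float)), coding="dosage012")


def random_binary(n, m, pi=0.1, seed=0) -> GenotypeMatrix:
    return generate_binary(SimConfig(n=n, m=m, pi=pi, seed=seed))


@pytest.fixture
def toy_binary_3x3():
    """Rows (1,1,0),(1,0,1),(0,1,1): the worked weighted-Jaccard example."""
    return binary_matrix([[1, 1, 0], [1, 0, 1], [0, 1, 1]])


@pytest.fixture
def toy_dosage_2x2():
    """G=[[0,2],[1,1]]: both GRM flavors equal [[1,-1],[-1,1]]."""
    return dosage_matrix([[0, 2], [1, 1]])


@pytest.fixture
def toy_columns_ajc():
    """Columns (1,1,0),(1,0,1),(1,0,0): s=(2,2,1), approximate Jaccard = A/4."""
    return binary_matrix([[1, 1, 1], [1, 0, 0], [0, 1, 0]])
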
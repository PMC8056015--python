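import numpy as np
import pytest
import scipy.sparse as sp

from svmatac import CellPeakMatrix, GroupAssignment, PeakSet, make_fixed_bins


def matrix_from_dense(dense, chrom="chr1", bin_size=5000, prefix="cell"):
    """Wrap a dense 0/1 array as a CellPeakMatrix over fixed bins."""
    dense = np.asarray(dense, dtype=np.int8)
    n, m = dense.shape
    peaks = make_fixed_bins({chrom: m * bin_size}, bin_size)
    barcodes = [f"{prefix}{i}" for i in range(n)]
    return CellPeakMatrix(sp.csr_matrix(dense), barcodes, peaks)


def groups_for(matrix, labels):
    return GroupAssignment.from_arrays(matrix.barcodes, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    dense = np.array(
        [
            [1, 0, 0, 1],
            [0, 1, 0, 0],
            [0, 0, 0, 1],
        ]
    )
    return matrix_from_dense(dense)
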
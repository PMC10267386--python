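import numpy as np
import pytest
import scipy.sparse
from hypothesis import given, settings, strategies as st

from casagm import (
    CSCForm,
    IntegrityError,
    MutationMatrix,
    TripletSet,
    coo_decode,
    coo_encode,
    csc_decode,
    csc_encode,
    csr_decode,
    csr_encode,
    csr_from_triplets,
)
from casagm.codecs import csc_to_triplets, csr_to_triplets

from conftest import random_matrix


class TestWorkedExample:
    def test_coo_arrays(self, worked_example):
        T = coo_encode(worked_example)
        assert T.I.tolist() == [0, 0, 1, 2, 2, 2]
        assert T.J.tolist() == [0, 2, 2, 0, 1, 2]
        assert T.V.tolist() == [1, 2, 3, 4, 5, 6]

    def test_csc_arrays(self, worked_example):
        C = csc_encode(worked_example)
        assert C.indptr.tolist() == [0, 2, 3, 6]
        assert C.indices.tolist() == [0, 2, 2, 0, 1, 2]
        assert C.values.tolist() == [1, 4, 5, 2, 3, 6]

    def test_csr_arrays(self, worked_example):
        C = csr_encode(worked_example)
        assert C.indptr.tolist() == [0, 2, 3, 6]
        assert C.indices.tolist() == [0, 2, 2, 0, 1, 2]
        assert C.values.tolist() == [1, 2, 3, 4, 5, 6]

    def test_coo_decode_numeric(self):
        T = TripletSet(I=np.array([0, 0, 1, 2, 2, 2]), J=np.array([0, 2, 2, 0, 1, 2]),
                       V=np.array([1, 2, 3, 4, 5, 6]), m=3, n=3)
        M = coo_decode(T)
        assert M.values.tolist() == [[1, 0, 2], [0, 0, 3], [4, 5, 6]]

    def test_csc_decode_numeric(self):
        C = CSCForm(indptr=np.array([0, 2, 3, 6]), indices=np.array([0, 2, 2, 0, 1, 2]),
                    values=np.array([1, 4, 5, 2, 3, 6]), m=3, n=3)
        M = csc_decode(C)
        assert M.values.tolist() == [[1, 0, 2], [0, 0, 3], [4, 5, 6]]


class TestDegenerate:
    def test_zero_matrix_encodings(self):
        M = MutationMatrix(["a", "b"], list("vwxyz"), np.zeros((2, 5), dtype=np.int64))
        assert coo_encode(M).nnz == 0
        assert csc_encode(M).indptr.tolist() == [0] * 6
        assert csr_encode(M).indptr.tolist() == [0, 0, 0]

    def test_empty_triplets_decode(self):
        T = TripletSet(I=np.array([], int), J=np.array([], int), V=np.array([], int), m=2, n=2)
        assert coo_decode(T).nnz == 0

    def test_empty_column_decode(self):
        C = CSCForm(indptr=np.array([0, 0]), indices=np.array([], int),
                    values=np.array([], int), m=3, n=1)
        assert csc_decode(C).nnz == 0


@st.composite
def small_matrices(draw):
    m = draw(st.integers(1, 8))
    n = draw(st.integers(1, 8))
    cells = draw(st.lists(st.integers(-9, 9), min_size=m * n, max_size=m * n))
    return MutationMatrix([f"s{i}" for i in range(m)], [f"g{j}" for j in range(n)],
                          np.array(cells, dtype=np.int64).reshape(m, n))


class TestProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(small_matrices())
    def test_roundtrip_and_cross_codec(self, M):
        T = coo_encode(M)
        csc = csc_encode(M)
        csr = csr_encode(M)
        # lossless round-trips
        assert coo_decode(T).equals(M, check_labels=False)
        assert csc_decode(csc).equals(M, check_labels=False)
        assert csr_decode(csr).equals(M, check_labels=False)
        # nnz conservation and cross-codec agreement
        assert T.nnz == csc.nnz == csr.nnz == M.nnz
        assert csr.indices.tolist() == T.J.tolist()
        assert csr.indptr.tolist()[-1] == T.nnz
        # row-major CSR stream equals the COO stream
        S = csr_to_triplets(csr)
        assert S.I.tolist() == T.I.tolist() and S.V.tolist() == T.V.tolist()
        # column-major CSC stream sorted row-major equals the COO stream
        C = csc_to_triplets(csc)
        order = np.lexsort((C.J, C.I))
        assert C.I[order].tolist() == T.I.tolist()
        assert C.J[order].tolist() == T.J.tolist()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(small_matrices())
    def test_transpose_duality(self, M):
        Mt = MutationMatrix(M.col_labels, M.row_labels, M.values.T.copy())
        csc = csc_encode(M)
        csr_t = csr_encode(Mt)
        assert csc.indptr.tolist() == csr_t.indptr.tolist()
        assert csc.indices.tolist() == csr_t.indices.tolist()
        assert csc.values.tolist() == csr_t.values.tolist()

    def test_scipy_oracle_agreement(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            M = random_matrix(rng, 20, 15, 0.1, signed=True)
            ref_csc = scipy.sparse.csc_matrix(M.values)
            ref_csr = scipy.sparse.csr_matrix(M.values)
            ref_coo = scipy.sparse.coo_matrix(M.values)
            mine_csc = csc_encode(M)
            mine_csr = csr_encode(M)
            T = coo_encode(M)
            assert mine_csc.indptr.tolist() == ref_csc.indptr.tolist()
            assert mine_csc.indices.tolist() == ref_csc.indices.tolist()
            assert mine_csc.values.tolist() == ref_csc.data.tolist()
            assert mine_csr.indptr.tolist() == ref_csr.indptr.tolist()
            assert mine_csr.indices.tolist() == ref_csr.indices.tolist()
            # scipy COO is row-major for dense input, matching canonical order
            assert T.I.tolist() == ref_coo.row.tolist()
            assert T.J.tolist() == ref_coo.col.tolist()

    def test_csr_from_triplets_matches_dense_encode(self):
        rng = np.random.default_rng(4)
        M = random_matrix(rng, 12, 9, 0.3)
        T = coo_encode(M)
        perm = rng.permutation(T.nnz)
        C = csr_from_triplets(T.I[perm], T.J[perm], T.V[perm], M.m, M.n)
        D = csr_encode(M)
        assert C.indptr.tolist() == D.indptr.tolist()
        assert C.indices.tolist() == D.indices.tolist()
        assert C.values.tolist() == D.values.tolist()


class TestIntegrityErrors:
    def test_duplicate_coordinate(self):
        T = TripletSet(I=np.array([0, 0]), J=np.array([1, 1]), V=np.array([1, 2]), m=2, n=2)
        with pytest.raises(IntegrityError, match="duplicate"):
            coo_decode(T)

    def test_index_out_of_bounds(self):
        T = TripletSet(I=np.array([5]), J=np.array([0]), V=np.array([1]), m=2, n=2)
        with pytest.raises(IntegrityError, match="bounds"):
            coo_decode(T)

    def test_explicit_zero_value(self):
        T = TripletSet(I=np.array([0]), J=np.array([0]), V=np.array([0]), m=1, n=1)
        with pytest.raises(IntegrityError, match="zero"):
            coo_decode(T)

    @pytest.mark.parametrize(
        "indptr,indices,values,msg",
        [
            ([0, 2, 1], [0, 1], [1, 2], "non-decreasing"),
            ([0, 1, 3], [0, 1], [1, 2], "lengths"),
            ([0, 1, 2], [0, 7], [1, 2], "bounds"),
            ([0, 2, 2], [1, 0], [1, 2], "increasing"),
        ],
    )
    def test_bad_csc_structure(self, indptr, indices, values, msg):
        C = CSCForm(indptr=np.array(indptr), indices=np.array(indices),
                    values=np.array(values), m=6, n=2)
        with pytest.raises(IntegrityError, match=msg):
            csc_decode(C)
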
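"""Gram-route SVD: accumulation, thin and top-k decompositions."""

import numpy as np
import pytest
import scipy.linalg

from diskfact import (
    GenotypeSpec,
    ParameterError,
    ResourceError,
    check_svd_reconstruction,
    eigendecompose,
    gram_accumulate,
    generate_genotypes,
    svd_thin,
    svd_topk,
)


def standardized_genotypes(tmp_path, n, m, seed, make_matrix):
    """Column-standardized dosage matrix as an in-memory array + handle."""
    spec = GenotypeSpec(n_individuals=n, n_markers=m, seed=seed)
    geno = generate_genotypes(spec, tmp_path / "geno.bin")
    g = geno.read().astype(np.float64)
    p = g.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    z = (g[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    return z, make_matrix(z)


class TestGramAccumulate:
    def test_all_ones_three_by_two(self, make_matrix):
        g = gram_accumulate(make_matrix(np.ones((3, 2))))
        assert np.array_equal(g.values, [[3.0, 3.0], [3.0, 3.0]])

    def test_identity(self, make_matrix):
        g = gram_accumulate(make_matrix(np.eye(2)))
        assert np.array_equal(g.values, np.eye(2))

    def test_tiled_accumulation_matches_dense_product(self, make_matrix, rng):
        a = rng.standard_normal((500, 20))
        mat = make_matrix(a)
        # budget of 100 rows' worth forces >= 5 tiles
        g = gram_accumulate(mat, tile_elements=100 * 20)
        dense = a.T @ a
        eps = np.finfo(np.float64).eps
        bound = 10 * eps * np.linalg.norm(a, 2) ** 2
        assert np.abs(g.values - dense).max() <= max(bound, 500 * eps)

    def test_result_exactly_symmetric(self, make_matrix, rng):
        a = rng.standard_normal((97, 13))
        g = gram_accumulate(make_matrix(a), tile_elements=10 * 13)
        assert np.array_equal(g.values, g.values.T)

    @pytest.mark.parametrize("budget_rows", [1, 7, 64, 500])
    def test_tiling_independence(self, make_matrix, rng, budget_rows):
        a = rng.standard_normal((120, 11))
        mat = make_matrix(a)
        ref = gram_accumulate(mat).values
        g = gram_accumulate(mat, tile_elements=budget_rows * 11).values
        eps = np.finfo(np.float64).eps
        assert np.abs(g - ref).max() <= 10 * eps * np.linalg.norm(a, 2) ** 2

    def test_oversized_gram_advises_eigen_route(self, make_matrix):
        mat = make_matrix(np.ones((2, 40)))
        with pytest.raises(ResourceError, match="eigendecompose"):
            gram_accumulate(mat, max_gram_elements=100)


class TestThinSVD:
    def test_padded_diagonal_singular_values(self, make_matrix):
        a = np.vstack([np.diag([3.0, 2.0, 1.0]), np.zeros((2, 3))])
        res = svd_thin(make_matrix(a))
        assert np.allclose(res.singular_values, [3.0, 2.0, 1.0])

    def test_single_column_closed_form(self, make_matrix):
        res = svd_thin(make_matrix(np.ones((4, 1))))
        assert res.singular_values[0] == pytest.approx(2.0)
        assert np.allclose(np.abs(res.right_vectors), [[1.0]])
        assert np.allclose(np.abs(res.left_vectors).ravel(), [0.5] * 4)
        # sign convention: largest-magnitude V entry positive
        assert res.right_vectors[0, 0] > 0

    def test_genotype_fixture_matches_dense_svd_oracle(
        self, tmp_path, make_matrix
    ):
        """200x15 standardized genotypes, single working precision:
        relative Euclidean error of sigma vs dense SVD below 1e-5."""
        z, mat = standardized_genotypes(tmp_path, 200, 15, 5, make_matrix)
        single = make_matrix(z, precision="single")
        res = svd_thin(single, precision="single")
        ref = scipy.linalg.svdvals(z)
        err = np.linalg.norm(res.singular_values.astype(np.float64) - ref)
        assert err / np.linalg.norm(ref) <= 1e-5

    def test_descending_order_and_orthonormality(self, tmp_path, make_matrix):
        z, mat = standardized_genotypes(tmp_path, 150, 12, 1, make_matrix)
        res = svd_thin(mat)
        s = res.singular_values
        assert np.all(np.diff(s) <= 0) and np.all(s >= 0)
        eps = np.finfo(np.float64).eps
        k = res.k
        assert np.abs(
            res.right_vectors.T @ res.right_vectors - np.eye(k)
        ).max() <= 50 * 150 * eps
        live = [j for j in range(k) if j not in res.zero_columns]
        u = res.left_vectors[:, live]
        assert np.abs(u.T @ u - np.eye(len(live))).max() <= 50 * 150 * eps

    def test_reconstruction_residual(self, tmp_path, make_matrix):
        z, mat = standardized_genotypes(tmp_path, 100, 10, 3, make_matrix)
        res = svd_thin(mat)
        assert check_svd_reconstruction(mat, res) <= 1e-12

    def test_energy_conservation(self, make_matrix, rng):
        a = rng.standard_normal((80, 9))
        mat = make_matrix(a)
        res = svd_thin(mat)
        g = gram_accumulate(mat)
        eps = np.finfo(np.float64).eps
        assert abs(
            np.sum(res.singular_values**2) - np.trace(g.values)
        ) <= 80 * eps * np.trace(g.values)

    def test_gram_eigen_consistency(self, make_matrix, rng, tmp_path):
        """Eigenvalues of A^T A from the eigen module equal sigma^2."""
        a = rng.standard_normal((60, 8))
        mat = make_matrix(a)
        res = svd_thin(mat)
        from conftest import as_diskmatrix

        gram_mat = as_diskmatrix(
            gram_accumulate(mat).values, tmp_path / "gram.bin"
        )
        lam = eigendecompose(gram_mat).eigenvalues[::-1]  # descending
        eps = np.finfo(np.float64).eps
        assert np.abs(res.singular_values**2 - lam).max() <= 10 * eps * lam[0] * 60

    def test_scale_equivariance(self, make_matrix, rng):
        a = rng.standard_normal((50, 6))
        r1 = svd_thin(make_matrix(a))
        r2 = svd_thin(make_matrix(3.0 * a))
        assert np.allclose(r2.singular_values, 3.0 * r1.singular_values)
        assert np.allclose(r2.right_vectors, r1.right_vectors, atol=1e-12)
        assert np.allclose(r2.left_vectors, r1.left_vectors, atol=1e-12)

    def test_wide_matrix_transposed_internally(self, make_matrix, rng):
        a = rng.standard_normal((3, 5))
        res = svd_thin(make_matrix(a))
        assert res.transposed
        assert res.left_vectors.shape == (3, 3)
        assert res.right_vectors.shape == (5, 3)
        ref = scipy.linalg.svdvals(a)
        assert np.allclose(res.singular_values, ref, atol=1e-10)
        recon = res.left_vectors * res.singular_values @ res.right_vectors.T
        assert np.allclose(recon, a, atol=1e-9)

    def test_disk_mode_left_vectors_file_backed(self, tmp_path, make_matrix):
        z, mat = standardized_genotypes(tmp_path, 90, 7, 2, make_matrix)
        mem = svd_thin(mat, mode="memory")
        dsk = svd_thin(mat, mode="disk")
        assert isinstance(dsk.left_vectors, np.memmap)
        assert np.array_equal(np.asarray(dsk.left_vectors), mem.left_vectors)
        dsk.cleanup()
        assert not dsk.workspace_paths

    def test_rank_deficient_columns_flagged_and_zeroed(self, make_matrix):
        a = np.ones((6, 3))  # rank one
        res = svd_thin(make_matrix(a))
        assert len(res.zero_columns) == 2
        for j in res.zero_columns:
            assert res.singular_values[j] == 0.0
            assert np.all(res.left_vectors[:, j] == 0.0)


class TestTopK:
    def test_padded_diagonal_top_two(self, make_matrix):
        a = np.vstack([np.diag([3.0, 2.0, 1.0]), np.zeros((2, 3))])
        res = svd_topk(make_matrix(a), k=2)
        assert np.allclose(res.singular_values, [3.0, 2.0])
        assert res.k == 2

    def test_k_equal_to_min_dim_rejected(self, make_matrix):
        """Only a strict subset of the spectrum may be requested."""
        mat = make_matrix(np.ones((5, 3)))
        with pytest.raises(ParameterError):
            svd_topk(mat, k=3)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_prefix_of_thin_svd_exactly(self, tmp_path, make_matrix, k):
        z, mat = standardized_genotypes(tmp_path, 300, 25, 8, make_matrix)
        full = svd_thin(mat)
        top = svd_topk(mat, k=k)
        assert np.array_equal(top.singular_values, full.singular_values[:k])
        assert np.array_equal(top.right_vectors, full.right_vectors[:, :k])
        # U is rebuilt from a k-column product; identical up to rounding
        assert np.allclose(
            top.left_vectors, full.left_vectors[:, :k], atol=1e-14
        )

    @pytest.mark.parametrize("k", [0, -1, 30])
    def test_out_of_range_k_rejected(self, make_matrix, k):
        with pytest.raises(ParameterError):
            svd_topk(make_matrix(np.ones((40, 20))), k=k)
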
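"""Distance-metric unit and property tests.

The load-bearing checks are the cross-route comparisons: the
Gram-decomposition path against per-pair evaluation, and the Pearson
pipeline against a hand-written correlation formula.
"""

import numpy as np
import pytest

from blockknn.metrics import (DataMatrix, MetricError, center_data,
                              compute_norms, cosine_block,
                              direct_distance_oracle, euclidean_sq_block,
                              gram_block, pearson_block)


def _dm(values):
    return DataMatrix(np.asarray(values, dtype=float))


class TestComputeNorms:
    def test_zero_matrix(self):
        assert compute_norms(_dm(np.zeros((3, 2)))).tolist() == [0.0, 0.0]

    def test_standard_basis(self):
        assert compute_norms(_dm(np.eye(2))).tolist() == [1.0, 1.0]

    def test_matches_sum_of_squares_loop(self, rng):
        vals = rng.standard_normal((5, 4))
        expected = [sum(vals[i, j] ** 2 for i in range(5)) for j in range(4)]
        np.testing.assert_allclose(compute_norms(_dm(vals)), expected,
                                   rtol=1e-12)

    def test_nonfinite_entry_names_column(self):
        vals = np.ones((3, 4))
        vals[1, 2] = np.nan
        with pytest.raises(MetricError, match="column 2"):
            _dm(vals)


class TestGramBlock:
    def test_single_unit_vector(self):
        x = _dm([[1.0], [0.0]])
        assert gram_block(x, x).tolist() == [[1.0]]

    def test_orthogonal_columns(self):
        x = _dm(np.eye(3))
        np.testing.assert_array_equal(gram_block(x, x), np.eye(3))

    def test_matches_nested_dot_loop(self, rng):
        a, b = rng.standard_normal((8, 5)), rng.standard_normal((8, 7))
        expected = [[float(a[:, i] @ b[:, j]) for j in range(7)]
                    for i in range(5)]
        np.testing.assert_allclose(gram_block(_dm(a), _dm(b)), expected,
                                   rtol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(MetricError, match="dimension mismatch"):
            gram_block(_dm(np.ones((3, 2))), _dm(np.ones((4, 2))))


class TestEuclideanSqBlock:
    def test_identical_point_is_zero(self):
        x = _dm([[1.0], [2.0]])
        nu = compute_norms(x)
        block = euclidean_sq_block(gram_block(x, x), nu, nu)
        assert block.values.tolist() == [[0.0]]

    def test_1d_hand_computation(self):
        a, b = _dm([[0.0]]), _dm([[3.0]])
        block = euclidean_sq_block(gram_block(a, b), compute_norms(a),
                                   compute_norms(b), 0, 1)
        assert block.values.tolist() == [[9.0]]

    def test_matches_direct_pairwise_loop(self, rng):
        a, b = rng.standard_normal((6, 20)), rng.standard_normal((6, 30))
        nu_a, nu_b = compute_norms(_dm(a)), compute_norms(_dm(b))
        block = euclidean_sq_block(gram_block(_dm(a), _dm(b)), nu_a, nu_b,
                                   0, 100)
        expected = [[float(((a[:, i] - b[:, j]) ** 2).sum())
                     for j in range(30)] for i in range(20)]
        assert np.abs(block.values - expected).max() < 1e-8

    def test_shape_mismatch(self):
        with pytest.raises(MetricError, match="does not match"):
            euclidean_sq_block(np.zeros((2, 3)), np.zeros(2), np.zeros(4))

    def test_symmetry_before_clamping(self, rng):
        vals = rng.standard_normal((10, 40))
        x = _dm(vals)
        nu = compute_norms(x)
        block = euclidean_sq_block(gram_block(x, x), nu, nu)
        np.testing.assert_allclose(block.values, block.values.T, rtol=1e-12)

    def test_nonnegative_and_zero_diagonal(self, rng):
        # near-duplicate columns provoke cancellation
        vals = np.repeat(rng.standard_normal((8, 5)), 4, axis=1)
        vals += 1e-9 * rng.standard_normal(vals.shape)
        x = _dm(vals)
        nu = compute_norms(x)
        block = euclidean_sq_block(gram_block(x, x), nu, nu)
        assert (block.values >= 0).all()
        assert np.diag(block.values).tolist() == [0.0] * 20


class TestCosineBlock:
    def test_identical_orthogonal_antipodal(self):
        x = _dm([[1.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
        nu = compute_norms(x)
        block = cosine_block(x, x, nu, nu)
        assert block.values[0, 0] == 0.0
        assert block.values[0, 1] == 1.0
        assert block.values[0, 2] == 2.0

    def test_zero_norm_column_is_error(self):
        x = _dm([[1.0, 0.0], [1.0, 0.0]])
        nu = compute_norms(x)
        with pytest.raises(MetricError, match="column 1"):
            cosine_block(x, x, nu, nu)

    def test_scale_invariance(self, rng):
        vals = rng.standard_normal((12, 30))
        scaled = vals * rng.uniform(0.1, 10.0, size=30)
        b1 = cosine_block(_dm(vals), _dm(vals), compute_norms(_dm(vals)),
                          compute_norms(_dm(vals)))
        b2 = cosine_block(_dm(scaled), _dm(scaled),
                          compute_norms(_dm(scaled)),
                          compute_norms(_dm(scaled)))
        np.testing.assert_allclose(b1.values, b2.values, rtol=1e-12, atol=0)


class TestCenterData:
    def test_identical_columns_become_zero(self):
        x = _dm(np.tile([[1.0], [2.0]], (1, 5)))
        assert (center_data(x).values == 0).all()

    def test_two_column_hand_computation(self):
        x = _dm([[0.0, 2.0], [0.0, 4.0]])
        np.testing.assert_array_equal(center_data(x).values,
                                      [[-1.0, 1.0], [-2.0, 2.0]])

    def test_dataset_mode_zeroes_per_dimension_means(self, rng):
        x = _dm(rng.standard_normal((6, 50)) + 3.0)
        means = center_data(x).values.mean(axis=1)
        assert np.abs(means).max() < 1e-12

    def test_per_vector_mode_zeroes_per_column_means(self, rng):
        x = _dm(rng.standard_normal((6, 50)) + 3.0)
        means = center_data(x, mode="per_vector").values.mean(axis=0)
        assert np.abs(means).max() < 1e-12


class TestPearson:
    def test_equals_cosine_of_centered_data(self, rng):
        x = _dm(rng.standard_normal((10, 25)) + 1.5)
        xc = center_data(x)
        nu = compute_norms(xc)
        p = pearson_block(xc, xc, nu, nu)
        c = cosine_block(xc, xc, nu, nu)
        assert np.abs(p.values - c.values).max() == 0.0

    def test_matches_textbook_correlation_dataset_centering(self, rng):
        vals = rng.standard_normal((10, 25)) + 1.5
        mu = vals.mean(axis=1, keepdims=True)
        expected = np.empty((25, 25))
        for i in range(25):
            for j in range(25):
                a, b = vals[:, i] - mu[:, 0], vals[:, j] - mu[:, 0]
                expected[i, j] = 1.0 - (a @ b) / np.sqrt((a @ a) * (b @ b))
        xc = center_data(_dm(vals))
        nu = compute_norms(xc)
        p = pearson_block(xc, xc, nu, nu)
        assert np.abs(p.values - np.maximum(expected, 0.0)).max() < 1e-10

    def test_per_vector_mode_matches_numpy_corrcoef(self, rng):
        vals = rng.standard_normal((10, 25))
        xc = center_data(_dm(vals), mode="per_vector")
        nu = compute_norms(xc)
        p = pearson_block(xc, xc, nu, nu)
        expected = 1.0 - np.corrcoef(vals.T)
        assert np.abs(p.values - np.maximum(expected, 0.0)).max() < 1e-10


class TestGramVsDirect:
    @pytest.mark.parametrize("n,d", [(50, 8), (200, 64), (500, 512)])
    def test_gram_path_matches_per_pair_path(self, n, d):
        g = np.random.default_rng(n + d)
        a = _dm(g.standard_normal((d, n)))
        b = _dm(g.standard_normal((d, n // 2)))
        nu_a, nu_b = compute_norms(a), compute_norms(b)
        via_gram = euclidean_sq_block(gram_block(a, b), nu_a, nu_b)
        direct = direct_distance_oracle(a, b, "euclidean_sq")
        assert np.abs(via_gram.values - direct.values).max() < 1e-8

    def test_direct_oracle_hand_values(self):
        a, b = _dm([[0.0]]), _dm([[3.0]])
        assert direct_distance_oracle(a, a).values.tolist() == [[0.0]]
        assert direct_distance_oracle(a, b, "euclidean_sq",
                                      0, 1).values.tolist() == [[9.0]]
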
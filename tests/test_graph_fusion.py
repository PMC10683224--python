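import numpy as np
import pytest

from oracles import gcn_oracle
from rgdfusion.graph_fusion import (
    GCNParams,
    ModelGraph,
    build_adjacency,
    gcn_forward,
    gcn_forward_t,
    init_gcn_params,
    model_similarity,
    normalize_adjacency,
)
from rgdfusion.nn import Tensor


class TestSimilarity:
    def test_identical_predictions(self):
        assert model_similarity([1, 0, 1], [1, 0, 1]) == 1.0

    def test_complementary_predictions(self):
        assert model_similarity([1, 0, 1], [0, 1, 0]) == 0.0

    def test_partial_agreement(self):
        assert model_similarity([1, 1, 0, 0], [1, 1, 0, 1]) == 0.75

    def test_errors(self):
        with pytest.raises(ValueError):
            model_similarity([], [])
        with pytest.raises(ValueError):
            model_similarity([1, 0], [1])


class TestAdjacency:
    def test_all_agreeing_models_divergence_zero(self):
        preds = [np.ones(10, dtype=int)] * 5
        np.testing.assert_array_equal(build_adjacency(preds, "a1s"),
                                      np.zeros((5, 5)))

    def test_a1_is_all_ones(self, rng):
        preds = [rng.integers(0, 2, 20) for _ in range(4)]
        np.testing.assert_array_equal(build_adjacency(preds, "a1"),
                                      np.ones((4, 4)))

    def test_a0_is_all_zeros(self, rng):
        preds = [rng.integers(0, 2, 20) for _ in range(4)]
        np.testing.assert_array_equal(build_adjacency(preds, "a0"),
                                      np.zeros((4, 4)))

    def test_similarity_divergence_complementarity(self, rng):
        preds = [rng.integers(0, 2, 30) for _ in range(5)]
        a_s = build_adjacency(preds, "as")
        a_1s = build_adjacency(preds, "a1s")
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose((a_s + a_1s)[off], 1.0)
        for A in (a_s, a_1s):
            assert ((A >= 0) & (A <= 1)).all()
            np.testing.assert_allclose(A, A.T)
            np.testing.assert_array_equal(np.diag(A), 0.0)

    def test_hyphenated_variant_aliases(self, rng):
        preds = [rng.integers(0, 2, 10) for _ in range(3)]
        np.testing.assert_array_equal(
            build_adjacency(preds, "A-1-S"), build_adjacency(preds, "a1s")
        )

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            build_adjacency([np.zeros(3), np.zeros(3)], "a2")


class TestNormalize:
    def test_zero_adjacency_maps_to_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((4, 4))),
                                   np.eye(4))

    def test_all_ones_2x2_closed_form(self):
        # A+I = [[2,1],[1,2]] has row sums 3, so the propagation matrix is
        # [[2/3,1/3],[1/3,2/3]]
        np.testing.assert_allclose(
            normalize_adjacency(np.ones((2, 2))),
            np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]]),
        )

    def test_complete_graph_2x2_uniform_propagation(self):
        # zero-diagonal complete graph: A+I all-ones, row sums 2 -> all 1/2
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(A), np.full((2, 2), 0.5))

    def test_symmetric_output(self, rng):
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        S = normalize_adjacency(A)
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestGCNForward:
    def test_single_node_first_layer_exact(self, rng):
        h0 = rng.standard_normal((1, 6))
        params = init_gcn_params(6, 4, 3, seed=0)
        fg = gcn_forward(ModelGraph(h0, np.zeros((1, 1))), params)
        h1 = np.maximum(h0 @ params.w0, 0)  # propagation matrix is [1]
        expected = np.maximum(h1 @ params.w1, 0).ravel()
        np.testing.assert_allclose(fg, expected, atol=1e-12)

    def test_zero_weights_zero_output(self, rng):
        h0 = rng.standard_normal((5, 6))
        params = GCNParams(w0=np.zeros((6, 4)), w1=np.zeros((4, 3)))
        fg = gcn_forward(ModelGraph(h0, np.ones((5, 5))), params)
        np.testing.assert_array_equal(fg, 0.0)
        assert fg.size == 5 * 3

    def test_matches_dense_oracle(self, rng):
        h0 = rng.standard_normal((5, 8))
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = init_gcn_params(8, 6, 4, seed=1)
        fg = gcn_forward(ModelGraph(h0, A), params)
        np.testing.assert_allclose(
            fg, gcn_oracle(h0, A, params.w0, params.w1), atol=1e-6
        )

    def test_permutation_consistency(self, rng):
        h0 = rng.standard_normal((5, 8))
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = init_gcn_params(8, 6, 4, seed=2)
        perm = np.array([3, 1, 4, 0, 2])
        fg = gcn_forward(ModelGraph(h0, A), params).reshape(5, 4)
        fg_p = gcn_forward(
            ModelGraph(h0[perm], A[np.ix_(perm, perm)]), params
        ).reshape(5, 4)
        np.testing.assert_allclose(fg_p, fg[perm], atol=1e-10)

    def test_a0_identity_weights_no_crosstalk(self, rng):
        """With the empty graph and identity weights each node's output is a
        function of its own features only."""
        h0 = rng.standard_normal((4, 6))
        params = GCNParams(w0=np.eye(6), w1=np.eye(6))
        fg = gcn_forward(ModelGraph(h0, np.zeros((4, 4))), params).reshape(4, 6)
        h0_mod = h0.copy()
        h0_mod[2] += 10.0
        fg_mod = gcn_forward(
            ModelGraph(h0_mod, np.zeros((4, 4))), params
        ).reshape(4, 6)
        np.testing.assert_array_equal(fg[[0, 1, 3]], fg_mod[[0, 1, 3]])
        assert not np.array_equal(fg[2], fg_mod[2])

    def test_training_path_matches_inference_path(self, rng):
        """The differentiable GCN used during head training computes the same
        FG as the numpy inference forward."""
        h0 = rng.standard_normal((7, 5, 8)).astype(np.float32)
        A = rng.random((5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        params = init_gcn_params(8, 6, 4, seed=3)
        S = normalize_adjacency(A)
        fg_t = gcn_forward_t(
            Tensor(h0), S,
            Tensor(params.w0.astype(np.float32)),
            Tensor(params.w1.astype(np.float32)),
        ).data
        fg = gcn_forward(ModelGraph(h0, A), params)
        np.testing.assert_allclose(fg_t, fg, atol=1e-4)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            gcn_forward(
                ModelGraph(rng.standard_normal((5, 8)), np.zeros((4, 4))),
                init_gcn_params(8, 4, 2),
            )
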
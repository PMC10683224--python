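import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgdfusion.graph_fusion import build_adjacency
from rgdfusion.heads import (
    EnsembleWeights,
    FocalParams,
    FusionModel,
    ensemble_predict,
    ensemble_weights,
    finetune_heads,
    focal_loss,
    focal_loss_tensor,
)
from rgdfusion.nn import Tensor


class TestFocalLoss:
    def test_closed_form_value(self):
        # y=1, p=0.5, alpha=0.25, gamma=2: 0.25 * 0.25 * ln 2
        expected = 0.25 * 0.25 * np.log(2)
        assert focal_loss(1, 0.5) == pytest.approx(expected, rel=1e-6)

    def test_perfect_prediction_near_zero(self):
        assert focal_loss([1, 0], [1 - 1e-9, 1e-9]) < 1e-6

    def test_gamma_zero_reduces_to_half_bce(self, rng):
        p = rng.uniform(0.05, 0.95, 20)
        y = rng.integers(0, 2, 20).astype(float)
        fl = focal_loss(y, p, FocalParams(alpha=0.5, gamma=0.0))
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert fl == pytest.approx(0.5 * bce, rel=1e-9)

    def test_monotonicity_in_probability(self):
        ps = np.linspace(0.01, 0.99, 200)
        pos = np.array([focal_loss(1, p) for p in ps])
        neg = np.array([focal_loss(0, p) for p in ps])
        assert (np.diff(pos) < 0).all()  # decreasing for y=1
        assert (np.diff(neg) > 0).all()  # increasing for y=0

    @settings(max_examples=50, derandomize=True)
    @given(
        p=st.floats(1e-6, 1 - 1e-6),
        alpha=st.floats(0.0, 1.0),
        gamma=st.floats(0.0, 5.0),
    )
    def test_nonnegative_for_any_parameters(self, p, alpha, gamma):
        params = FocalParams(alpha=alpha, gamma=gamma)
        assert focal_loss(1, p, params) >= 0.0
        assert focal_loss(0, p, params) >= 0.0

    def test_invalid_labels(self):
        with pytest.raises(ValueError):
            focal_loss([2], [0.5])
        with pytest.raises(ValueError):
            focal_loss([1], [0.5], FocalParams(alpha=1.5))

    def test_tensor_version_matches_numpy(self, rng):
        y = rng.integers(0, 2, 32).astype(np.float32)
        p = rng.uniform(0.02, 0.98, 32).astype(np.float32)
        lt = focal_loss_tensor(y, Tensor(p)).data
        assert lt == pytest.approx(focal_loss(y, p), abs=1e-5)


class TestEnsemble:
    def test_equal_accuracies_equal_weights(self):
        w = ensemble_weights([0.9] * 5)
        np.testing.assert_allclose(w.weights, 0.2)

    def test_proportional_weights(self):
        w = ensemble_weights([0.8, 0.2])
        np.testing.assert_allclose(w.weights, (0.8, 0.2))

    def test_weights_sum_to_one(self, rng):
        for _ in range(5):
            acc = rng.uniform(0.05, 1.0, 7)
            assert sum(ensemble_weights(acc).weights) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ensemble_weights([0.0, 0.0])

    def test_weighted_average(self):
        w = ensemble_weights([0.8, 0.2])
        assert ensemble_predict([1.0, 0.0], w) == pytest.approx(0.8)

    def test_unanimous_probability(self):
        w = ensemble_weights([0.5, 0.7, 0.9])
        assert ensemble_predict([1.0, 1.0, 1.0], w) == pytest.approx(1.0)

    def test_convex_combination_and_permutation_invariance(self, rng):
        probs = rng.uniform(0, 1, 5)
        acc = rng.uniform(0.1, 1, 5)
        w = ensemble_weights(acc)
        P = ensemble_predict(probs, w)
        assert probs.min() <= P <= probs.max()
        perm = rng.permutation(5)
        P2 = ensemble_predict(probs[perm], ensemble_weights(acc[perm]))
        assert P == pytest.approx(P2, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ensemble_predict([0.5], ensemble_weights([0.5, 0.5]))


def _toy_fusion_inputs(rng, n=60, n_models=3, fd=6, fr_dim=5):
    """Linearly separable toy features for head training."""
    y = np.repeat([0, 1], n // 2)
    feats = rng.standard_normal((n, n_models, fd)).astype(np.float32)
    feats[:, :, 0] += 2.0 * y[:, None]  # class signal in every model
    fr = rng.standard_normal((n, fr_dim)).astype(np.float32)
    fr[:, 0] += 1.5 * y
    preds = [
        (feats[:, i, 0] > 1.0).astype(int) for i in range(n_models)
    ]
    A = build_adjacency(preds, "a1s")
    return feats, fr, A, y


class TestFinetuneHeads:
    def test_deterministic_under_seed(self, rng):
        feats, fr, A, y = _toy_fusion_inputs(rng)
        m1 = finetune_heads(feats, fr, A, y, epochs=5, seed=3)
        m2 = finetune_heads(feats, fr, A, y, epochs=5, seed=3)
        for p1, p2 in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(p1, p2)

    def test_learns_separable_task(self, rng):
        feats, fr, A, y = _toy_fusion_inputs(rng)
        model = finetune_heads(feats, fr, A, y, epochs=60, lr=3e-3, seed=0)
        probs = model.predict(feats, fr)
        for p in probs:
            assert ((p >= 0.5).astype(int) == y).mean() > 0.9

    def test_zero_radiomics_reduces_to_feature_probe(self, rng):
        feats, fr, A, y = _toy_fusion_inputs(rng)
        model = finetune_heads(feats, np.zeros_like(fr), A, y, epochs=10,
                               seed=1)
        probs = model.predict(feats, np.zeros_like(fr))
        assert probs.shape == (3, len(y))
        assert np.isfinite(probs).all()

    def test_empty_radiomics_block_supported(self, rng):
        feats, fr, A, y = _toy_fusion_inputs(rng)
        fr0 = np.zeros((len(y), 0), dtype=np.float32)
        model = finetune_heads(feats, fr0, A, y, epochs=5, seed=1)
        assert model.predict(feats, fr0).shape == (3, len(y))

    def test_misaligned_inputs_rejected(self, rng):
        feats, fr, A, y = _toy_fusion_inputs(rng)
        with pytest.raises(ValueError):
            finetune_heads(feats, fr[:-1], A, y, epochs=1)

    def test_heads_keep_backbone_accuracy(self, small_cohort):
        """Fused heads (backbone features + FR + FG) retain at least the
        frozen backbone's own training accuracy (within 0.02)."""
        from rgdfusion.backbones import (
            BackboneSpec,
            OptimizerConfig,
            build_backbone,
            train_backbone,
        )
        from rgdfusion.cohort import preprocess_volume
        from rgdfusion.radiomics import HOGParams, radiomics_vector

        X, y, _ = small_cohort
        preds, feats, accs = [], [], []
        for name in ("alexnet", "googlenet"):
            net = build_backbone(BackboneSpec(name=name, feature_dim=16),
                                 seed=5)
            p = train_backbone(net, X, y, epochs=6,
                               optimizer=OptimizerConfig(lr=1e-3), seed=5)
            preds.append(p)
            accs.append((p == y).mean())
            feats.append(net.apply(X).features)
        fr = np.stack([radiomics_vector(v).fr for v in X]).astype(np.float32)
        A = build_adjacency(preds, "a1s")
        model = finetune_heads(np.stack(feats, axis=1), fr, A, y,
                               gcn_hidden=16, gcn_out=8, epochs=25, seed=6)
        probs = model.predict(np.stack(feats, axis=1), fr)
        for i, p in enumerate(probs):
            head_acc = ((p >= 0.5).astype(int) == y).mean()
            assert head_acc >= accs[i] - 0.02
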
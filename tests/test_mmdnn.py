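import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodiff.datamodel import FeatureSetSpec
from neurodiff.mmdnn import (
    ClassifierModel,
    TrainConfig,
    branch_layer_sizes,
    class_weights,
    early_stopping_controller,
    load_model,
    predict,
    pretrain_branches,
    save_model,
    train_mmdnn,
    weighted_cross_entropy,
)

TWO_BLOCKS = (FeatureSetSpec("volume", 500, 16), FeatureSetSpec("thickness", 500, 8))

FAST = dict(
    lr=5e-3, batch_size=32, dropout=0.5, patience=8,
    pretrain_epochs=40, fusion_epochs=40, finetune_epochs=20, max_epochs=40,
    fusion_hidden=(60, 30),
)


def two_block_cohort(n_per_class=60, effect=3.0, seed=0, signal_block=0):
    """Signal confined to one block: class shifts on disjoint features."""
    rng = np.random.default_rng(seed)
    dims = [s.dimension for s in TWO_BLOCKS]
    total = sum(dims)
    x = rng.normal(size=(3 * n_per_class, total))
    y = np.repeat([0, 1, 2], n_per_class)
    offset = 0 if signal_block == 0 else dims[0]
    for j in range(3):  # atrophy-like shifts over a few features per class
        x[y == 1, offset + j] += effect
        x[y == 2, offset + 3 + j] += effect
    perm = rng.permutation(x.shape[0])
    return x[perm], y[perm]


class TestBranchLayerSizes:
    def test_frozen_examples(self):
        assert branch_layer_sizes(131) == [393, 98, 50]
        assert branch_layer_sizes(1488) == [4464, 1116, 50]

    @given(st.integers(min_value=17, max_value=5000))
    def test_sizes_decrease_after_first_layer(self, n):
        # the expansion layer 3N dominates every later layer once N > 16
        a, b, c = branch_layer_sizes(n)
        assert a > b and a > c
        assert c == 50


class TestClassWeights:
    def test_inverse_proportion(self):
        labels = [0] * 300 + [1] * 100 + [2] * 100
        w = class_weights(labels, 3)
        assert np.allclose(w, [500 / 300, 5.0, 5.0])

    def test_balanced_equal(self):
        w = class_weights([0, 1, 2] * 10, 3)
        assert np.allclose(w, w[0])

    def test_absent_class_zero(self):
        w = class_weights([0, 0, 1, 1], 4)
        assert w[2] == 0.0 and w[3] == 0.0
        assert np.allclose(w[:2], [2.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights([], 3)


class TestWeightedCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert weighted_cross_entropy(probs, [0, 1, 2], np.ones(3)) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        probs = np.array([[0.5, 0.3, 0.2], [0.25, 0.25, 0.5]])
        loss = weighted_cross_entropy(probs, [0, 0], np.ones(3))
        assert loss == pytest.approx((np.log(2) + np.log(4)) / 2, abs=1e-9)

    def test_unit_weights_match_unweighted(self, rng):
        probs = rng.dirichlet(np.ones(3), size=20)
        labels = rng.integers(0, 3, size=20)
        loss = weighted_cross_entropy(probs, labels, np.ones(3))
        unweighted = -np.log(probs[np.arange(20), labels]).mean()
        assert loss == pytest.approx(unweighted, abs=1e-12)

    def test_scalar_loop_oracle(self, rng):
        for _ in range(10):
            n, k = 17, 4
            probs = rng.dirichlet(np.ones(k), size=n)
            labels = rng.integers(0, k, size=n)
            weights = rng.uniform(0.1, 5.0, size=k)
            total = 0.0
            for i in range(n):
                total -= weights[labels[i]] * np.log(max(probs[i, labels[i]], 1e-12))
            assert weighted_cross_entropy(probs, labels, weights) == pytest.approx(
                total / n, abs=1e-6
            )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.ones((2, 3)) / 3, [0], np.ones(3))


class TestEarlyStopping:
    def test_strictly_decreasing_never_stops(self):
        stop, best = early_stopping_controller(np.linspace(1, 0.1, 50), patience=20)
        assert stop is None and best == 50

    def test_flat_after_minimum(self):
        losses = [1.0, 0.9, 0.8, 0.7, 0.5] + [0.5] * 30
        stop, best = early_stopping_controller(losses, patience=20)
        assert (stop, best) == (25, 5)

    def test_smallest_case(self):
        stop, best = early_stopping_controller([1.0, 0.9, 0.95], patience=1)
        assert (stop, best) == (3, 2)

    def test_invalid_patience(self):
        with pytest.raises(ValueError):
            early_stopping_controller([1.0], patience=0)


class TestModelStructure:
    def test_seven_blocks_and_probability_rows(self):
        model = ClassifierModel(TWO_BLOCKS, rng=np.random.default_rng(0))
        assert model.n_mlp_blocks == len(TWO_BLOCKS) + 1
        x = np.random.default_rng(1).normal(size=(5, model.input_dim))
        probs, labels = predict(model, x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert labels.shape == (5,)

    def test_default_six_block_model_has_seven_mlps(self):
        from neurodiff.datamodel import scaled_feature_sets

        model = ClassifierModel(scaled_feature_sets(0.02), rng=np.random.default_rng(0))
        assert model.n_mlp_blocks == 7

    def test_argmax_and_tie_break(self):
        assert np.argmax([0.2, 0.5, 0.3]) == 1  # AD in NC/AD/FTD order
        assert np.argmax([0.4, 0.4, 0.2]) == 0  # tie -> lowest index (NC)

    def test_row_permutation_equivariance(self):
        model = ClassifierModel(TWO_BLOCKS, rng=np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(7, model.input_dim))
        perm = np.random.default_rng(4).permutation(7)
        probs, _ = predict(model, x)
        probs_perm, _ = predict(model, x[perm])
        assert np.allclose(probs[perm], probs_perm)

    def test_dimension_mismatch_rejected(self):
        model = ClassifierModel(TWO_BLOCKS, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((2, 5)))

    def test_inference_is_deterministic(self):
        # dropout must be disabled at inference
        model = ClassifierModel(TWO_BLOCKS, rng=np.random.default_rng(5))
        x = np.random.default_rng(6).normal(size=(4, model.input_dim))
        p1, _ = predict(model, x)
        p2, _ = predict(model, x)
        assert np.array_equal(p1, p2)


class TestTraining:
    def test_same_seed_same_losses(self):
        x, y = two_block_cohort(n_per_class=20, seed=1)
        cfg = TrainConfig(seed=11, **{**FAST, "pretrain_epochs": 3,
                                      "fusion_epochs": 3, "finetune_epochs": 2})
        _, h1 = train_mmdnn(x, y, cfg, specs=TWO_BLOCKS)
        _, h2 = train_mmdnn(x, y, cfg, specs=TWO_BLOCKS)
        assert h1["finetune"].val_losses == h2["finetune"].val_losses
        assert h1["fusion"].train_losses == h2["fusion"].train_losses

    def test_recovery_on_separable_cohort(self):
        x, y = two_block_cohort(n_per_class=60, effect=3.0, seed=2)
        cfg = TrainConfig(seed=0, **FAST)
        model, _ = train_mmdnn(x[:150], y[:150], cfg, specs=TWO_BLOCKS)
        acc = (model.predict_proba(x[150:]).argmax(axis=1) == y[150:]).mean()
        assert acc > 0.9

    def test_null_cohort_accuracy_near_chance(self):
        x, y = two_block_cohort(n_per_class=40, effect=0.0, seed=3)
        cfg = TrainConfig(seed=0, **FAST)
        model, _ = train_mmdnn(x[:90], y[:90], cfg, specs=TWO_BLOCKS)
        acc = (model.predict_proba(x[90:]).argmax(axis=1) == y[90:]).mean()
        # 99% binomial band around the 1/3 chance rate, n = 30
        band = 2.576 * np.sqrt((1 / 3) * (2 / 3) / 30)
        assert acc < 1 / 3 + band + 0.1  # wide guard: no leakage-driven skill

    def test_fused_model_close_to_best_single_branch(self):
        # fusion should not lose much relative to either block alone
        gaps = []
        for seed in (0, 1, 2):
            x, y = two_block_cohort(n_per_class=50, effect=2.0, seed=seed,
                                    signal_block=seed % 2)
            cfg = TrainConfig(seed=seed, **FAST)
            fused, _ = train_mmdnn(x[:120], y[:120], cfg, specs=TWO_BLOCKS)
            fused_acc = (fused.predict_proba(x[120:]).argmax(1) == y[120:]).mean()
            branch_accs = []
            for bi, spec in enumerate(TWO_BLOCKS):
                sl = slice(0, 16) if bi == 0 else slice(16, 24)
                solo, _ = train_mmdnn(
                    x[:120, sl], y[:120], cfg, specs=(spec,)
                )
                branch_accs.append(
                    (solo.predict_proba(x[120:, sl]).argmax(1) == y[120:]).mean()
                )
            gaps.append(fused_acc - max(branch_accs))
        assert np.median(gaps) >= -0.02

    def test_non_finite_input_aborts_with_diagnostics(self):
        x, y = two_block_cohort(n_per_class=10, seed=4)
        x[0, 0] = np.inf
        cfg = TrainConfig(seed=0, **{**FAST, "pretrain_epochs": 2})
        with pytest.raises(RuntimeError, match="non-finite"):
            pretrain_branches(x, y, cfg, specs=TWO_BLOCKS)

    def test_checkpoint_roundtrip(self, tmp_path):
        x, y = two_block_cohort(n_per_class=15, seed=5)
        cfg = TrainConfig(seed=0, **{**FAST, "pretrain_epochs": 2,
                                     "fusion_epochs": 2, "finetune_epochs": 1})
        model, _ = train_mmdnn(x, y, cfg, specs=TWO_BLOCKS)
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.allclose(back.predict_proba(x[:5]), model.predict_proba(x[:5]))
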
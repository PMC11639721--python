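"""Network contracts: shapes, determinism, loss, learnability, ablation."""

import numpy as np
import pytest

from ecgfusion.fca import FcaConfig
from ecgfusion.network import (
    ModelConfig,
    ResNetFca,
    TrainConfig,
    build_model,
    label_smoothing_loss,
    predict,
    train,
)

# a deliberately small architecture used throughout this file
TINY = dict(
    image_size=32,
    stem_channels=8,
    block_channels=(8, 16, 16, 16),
    block_strides=(1, 2, 2, 1),  # keeps the last feature map 2x2
    fca=FcaConfig(n_freq=4, reduction=4),
    dropout_p=0.5,
)


def _toy_separable(n_per_class=24, size=32, seed=0):
    """Two classes of images separated by a gross spatial pattern."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            img = rng.normal(0, 0.1, (3, size, size)).astype(np.float32)
            if cls == 0:
                img[:, : size // 2, :] += 1.0
            else:
                img[:, size // 2 :, :] += 1.0
            xs.append(img)
            ys.append(cls)
    return np.stack(xs), np.asarray(ys)


class TestBuildModel:
    def test_forward_gives_simplex_probabilities(self):
        model, n_params = build_model(ModelConfig(**TINY), seed=0)
        assert n_params > 0
        x = np.random.default_rng(0).normal(size=(4, 3, 32, 32))
        probs = model.predict_proba(x)
        assert probs.shape == (4, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_initial_parameters(self):
        m1, _ = build_model(ModelConfig(**TINY), seed=3)
        m2, _ = build_model(ModelConfig(**TINY), seed=3)
        for (k1, p1, _), (k2, p2, _) in zip(m1.parameters(), m2.parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1, p2)

    def test_block_count_is_fixed_at_four_stages(self):
        with pytest.raises(ValueError):
            ModelConfig(**{**TINY, "block_channels": (8, 16)}).validate()

    def test_depth_ablation_via_repeats(self):
        cfg = ModelConfig(**{**TINY, "block_repeats": (2, 1, 1, 1)})
        model = ResNetFca(cfg, seed=0)
        assert len(model.blocks) == 5

    def test_fca_divisibility_enforced(self):
        bad = ModelConfig(**{**TINY, "block_channels": (6, 16, 16, 16)})
        with pytest.raises(ValueError):
            bad.validate()

    def test_wrong_input_shape_rejected(self):
        model, _ = build_model(ModelConfig(**TINY), seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((2, 3, 16, 16)))


class TestLabelSmoothingLoss:
    def test_zero_eps_is_cross_entropy(self):
        p = np.array([[0.7, 0.2, 0.1]])
        assert label_smoothing_loss(p, [0], eps=0.0) == pytest.approx(-np.log(0.7))

    def test_uniform_probabilities_give_log_k(self):
        k = 5
        p = np.full((3, k), 1.0 / k)
        for eps in (0.0, 0.1, 0.5):
            assert label_smoothing_loss(p, [0, 2, 4], eps) == pytest.approx(np.log(k))

    def test_hand_computed_smoothed_case(self):
        p = np.array([[0.9, 0.025, 0.025, 0.025, 0.025]])
        eps = 0.1
        # y' = 0.9*onehot + 0.02 everywhere -> weights (0.92, 0.02 x4)
        expected = -(0.92 * np.log(0.9) + 4 * 0.02 * np.log(0.025))
        assert label_smoothing_loss(p, [0], eps) == pytest.approx(expected)


class TestTraining:
    def test_separable_toy_reaches_perfect_validation(self):
        x, y = _toy_separable()
        xv, yv = _toy_separable(8, seed=1)
        model = ResNetFca(ModelConfig(**{**TINY, "n_classes": 2}), seed=0)
        hist = train(model, x, y, xv, yv,
                     TrainConfig(batch_size=16, max_epochs=5, seed=0,
                                 learning_rate=3e-3))
        assert max(hist.val_accuracy) == 1.0

    def test_training_loss_decreases_early(self):
        x, y = _toy_separable()
        xv, yv = _toy_separable(8, seed=1)
        model = ResNetFca(ModelConfig(**{**TINY, "n_classes": 2}), seed=0)
        hist = train(model, x, y, xv, yv,
                     TrainConfig(batch_size=16, max_epochs=3, seed=0))
        assert hist.train_loss[2] < hist.train_loss[0]

    def test_seeded_rerun_is_identical(self):
        x, y = _toy_separable(n_per_class=8)
        xv, yv = _toy_separable(4, seed=1)
        hists = []
        for _ in range(2):
            model = ResNetFca(ModelConfig(**{**TINY, "n_classes": 2}), seed=5)
            hists.append(train(model, x, y, xv, yv,
                               TrainConfig(batch_size=8, max_epochs=2, seed=5)))
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_accuracy == hists[1].val_accuracy

    def test_best_checkpoint_is_restored(self):
        x, y = _toy_separable(n_per_class=8)
        xv, yv = _toy_separable(4, seed=1)
        model = ResNetFca(ModelConfig(**{**TINY, "n_classes": 2}), seed=0)
        hist = train(model, x, y, xv, yv,
                     TrainConfig(batch_size=8, max_epochs=4, seed=0))
        _, labels = predict(model, xv)
        restored_acc = float((labels == yv).mean())
        assert restored_acc == pytest.approx(hist.val_accuracy[hist.best_epoch])

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0).validate()

    def test_capacity_overfits_random_labels(self):
        """64 random images with random labels can be memorised."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(64, 3, 32, 32)).astype(np.float32)
        y = rng.integers(0, 2, 64)
        model = ResNetFca(
            ModelConfig(**{**TINY, "n_classes": 2, "dropout_p": 0.0}), seed=0
        )
        train(model, x, y, x, y,
              TrainConfig(batch_size=16, max_epochs=30, seed=0,
                          learning_rate=3e-3, label_smoothing_eps=0.0))
        _, labels = predict(model, x)
        assert (labels == y).mean() == 1.0


class TestPredict:
    def test_rows_are_simplex_and_ties_break_low(self):
        model, _ = build_model(ModelConfig(**TINY), seed=0)
        x = np.random.default_rng(1).normal(size=(6, 3, 32, 32))
        probs, labels = predict(model, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))

    def test_eval_mode_is_deterministic_for_duplicates(self):
        model, _ = build_model(ModelConfig(**TINY), seed=0)
        x0 = np.random.default_rng(2).normal(size=(1, 3, 32, 32))
        x = np.repeat(x0, 4, axis=0)
        probs, _ = predict(model, x)
        for row in probs[1:]:
            np.testing.assert_array_equal(row, probs[0])


class TestFcaAblation:
    def test_disabling_fca_changes_predictions(self):
        """The attention lever is live: identity attention alters outputs."""
        x = np.random.default_rng(3).normal(size=(4, 3, 32, 32))
        on = ResNetFca(ModelConfig(**TINY), seed=0).predict_proba(x)
        off = ResNetFca(
            ModelConfig(**{**TINY, "fca_enabled": False}), seed=0
        ).predict_proba(x)
        assert np.abs(on - off).max() > 1e-6
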
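"""Model assembly, augmentation, schedules and the training loop."""

import numpy as np
import pytest

from dermattn import data_io, training
from dermattn.synthetic_data import generate_arrays, imbalanced_triplet_spec
from dermattn.training import (
    EarlyStopping, LesionClassifier, ReduceLROnPlateau, TinyBackbone,
    TrainConfig, augment, build_model, evaluate, load_checkpoint,
    save_checkpoint, train,
)


def small_config(**kw):
    base = dict(seed=0, augment=False, n_attention_maps=2,
                backbone_channels=(4, 8), max_epochs=5)
    base.update(kw)
    return TrainConfig(**base)


def toy_data(seed=0, counts=(40, 40), size=(16, 16)):
    from test_synthetic_data import two_color_spec
    spec = two_color_spec(class_counts=counts, image_size=size, seed=seed)
    images, labels, _ = generate_arrays(spec)
    x = data_io.preprocess_pixels(images, "symmetric")
    tr, va = data_io.split_dataset(len(labels), (0.8, 0.2), seed=seed,
                                   stratify_labels=labels)
    return (x[tr], None, labels[tr]), (x[va], None, labels[va])


class TestBuildModel:
    def test_probabilities_sum_to_one(self, rng):
        model = build_model(small_config(), n_classes=3, input_shape=(16, 16))
        probs = model.forward(rng.normal(size=(4, 16, 16, 3)))
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_metadata_branch_widens_classifier_input(self):
        cfg = small_config(use_metadata=True, meta_units=32)
        model = build_model(cfg, n_classes=3, input_shape=(16, 16), meta_dim=10)
        assert model.classifier.W.value.shape[0] == model.image_feature_dim + 32

    def test_same_seed_identical_initial_parameters(self):
        m1 = build_model(small_config(), n_classes=2, input_shape=(16, 16))
        m2 = build_model(small_config(), n_classes=2, input_shape=(16, 16))
        for a, b in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(a.value, b.value)

    def test_metadata_required_when_built_with_branch(self, rng):
        cfg = small_config(use_metadata=True, meta_units=8)
        model = build_model(cfg, n_classes=2, input_shape=(16, 16), meta_dim=4)
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(2, 16, 16, 3)))

    def test_parameter_count_reported(self):
        model = build_model(small_config(), n_classes=3, input_shape=(16, 16))
        assert model.n_parameters() == sum(p.value.size for p in model.params()) > 0


class TestAugment:
    def test_all_transforms_disabled_is_identity(self, rng):
        cfg = small_config(rotation_range=0, shift_range=0, zoom_range=0,
                           horizontal_flip=False, vertical_flip=False)
        x = rng.normal(size=(8, 8, 3))
        np.testing.assert_array_equal(augment(x, rng, cfg), x)

    def test_constant_image_invariant_under_warp(self, rng):
        cfg = small_config()  # full rotation/shift/zoom/flips
        x = np.full((12, 12, 3), 3.25)
        np.testing.assert_allclose(augment(x, rng, cfg), x, atol=1e-9)

    def test_fixed_rng_reproducible(self):
        cfg = small_config()
        x = np.random.default_rng(2).normal(size=(10, 10, 3))
        a = augment(x, np.random.default_rng(9), cfg)
        b = augment(x, np.random.default_rng(9), cfg)
        np.testing.assert_array_equal(a, b)

    def test_shape_and_finiteness_preserved(self, rng):
        cfg = small_config()
        x = rng.normal(size=(9, 13, 3))
        out = augment(x, rng, cfg)
        assert out.shape == x.shape and np.isfinite(out).all()


class TestSchedules:
    def test_plateau_sequence_floored(self):
        sched = ReduceLROnPlateau(factor=0.2, patience=1, min_lr=1e-7,
                                  initial_lr=1e-3)
        sched.step(0.5)  # first epoch establishes the best
        seen = [sched.step(0.5) for _ in range(8)]
        np.testing.assert_allclose(
            seen, [2e-4, 4e-5, 8e-6, 1.6e-6, 3.2e-7, 1e-7, 1e-7, 1e-7])

    def test_early_stop_fires_at_patience_plus_one(self):
        stopper = EarlyStopping(patience=3)
        fired_at = None
        for epoch in range(1, 20):
            if stopper.step(0.5, epoch):
                fired_at = epoch
                break
        assert fired_at == 4  # 1 best-setting epoch + patience

    def test_improvement_resets_patience(self):
        stopper = EarlyStopping(patience=2)
        metrics = [0.1, 0.2, 0.15, 0.3, 0.3, 0.3]
        fires = [stopper.step(m, e) for e, m in enumerate(metrics, 1)]
        assert fires == [False, False, False, False, False, True]
        assert stopper.best_epoch == 4


class TestTrainLoop:
    def test_frozen_model_stops_after_patience_plus_one_epochs(self):
        train_set, val_set = toy_data()
        cfg = small_config(learning_rate=1e-30, early_stop_patience=1,
                           max_epochs=20)
        model = build_model(cfg, n_classes=2, input_shape=(16, 16))
        hist = train(model, train_set, val_set, cfg)
        assert hist["epochs_run"] == 2

    def test_separable_two_class_training_accuracy(self):
        train_set, val_set = toy_data(seed=1, counts=(100, 100))
        # standard Adam epsilon for the sanity run: the damped default is
        # tuned for long schedules, not a 50-epoch toy fit
        cfg = small_config(max_epochs=50, early_stop_patience=50,
                           optimizer_epsilon=1e-8)
        model = build_model(cfg, n_classes=2, input_shape=(16, 16))
        hist = train(model, train_set, val_set, cfg)
        assert max(hist["train_acc"]) > 0.95

    def test_loss_decreases_for_all_weight_schemes(self):
        train_set, val_set = toy_data(seed=2, counts=(60, 30))
        for scheme in ("none", "original", "balanced"):
            cfg = small_config(max_epochs=8, weight_scheme=scheme)
            model = build_model(cfg, n_classes=2, input_shape=(16, 16))
            hist = train(model, train_set, val_set, cfg)
            assert np.mean(hist["train_loss"][-2:]) < hist["train_loss"][0]

    def test_empty_training_class_with_weighting_is_hard_error(self):
        (xt, _, yt), val = toy_data()
        yt = np.zeros_like(yt)  # class 1 vanishes
        cfg = small_config(weight_scheme="balanced")
        model = build_model(cfg, n_classes=2, input_shape=(16, 16))
        with pytest.raises(ValueError, match="every class"):
            train(model, (xt, None, yt), val, cfg)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = small_config()
        model = build_model(cfg, n_classes=2, input_shape=(16, 16))
        x = rng.normal(size=(3, 16, 16, 3))
        before = model.forward(x)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        fresh = build_model(small_config(seed=99), n_classes=2, input_shape=(16, 16))
        load_checkpoint(fresh, tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(fresh.forward(x), before)


class TestEvaluate:
    class UniformStub:
        n_classes = 2

        def forward(self, x, meta=None, training=False):
            return np.full((len(x), 2), 0.5)

    def test_deterministic_reports(self):
        train_set, val_set = toy_data()
        cfg = small_config(max_epochs=2)
        model = build_model(cfg, n_classes=2, input_shape=(16, 16))
        train(model, train_set, val_set, cfg)
        r1 = evaluate(model, val_set)
        r2 = evaluate(model, val_set)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.accuracy == r2.accuracy

    def test_uniform_stub_on_balanced_data(self, rng):
        x = rng.normal(size=(40, 4, 4, 3))
        y = np.array([0, 1] * 20)
        rep = evaluate(self.UniformStub(), (x, None, y))
        assert rep.accuracy == pytest.approx(0.5)  # argmax ties -> class 0

    def test_perfect_memorization_stub(self, rng):
        x = rng.normal(size=(10, 4, 4, 3))
        y = np.array([0, 1] * 5)

        class Oracle:
            n_classes = 2

            def __init__(self):
                self.i = 0

            def forward(self, xb, meta=None, training=False):
                out = np.eye(2)[y[self.i:self.i + len(xb)]]
                self.i += len(xb)
                return out

        rep = evaluate(Oracle(), (x, None, y))
        assert rep.accuracy == 1.0
        np.testing.assert_allclose(rep.f1, 1.0)
        np.testing.assert_allclose(rep.auc, 1.0)

    def test_empty_test_set_error(self):
        with pytest.raises(ValueError):
            evaluate(self.UniformStub(), (np.empty((0, 4, 4, 3)), None, np.empty(0, int)))


def test_backbone_interface_contract(rng):
    bb = TinyBackbone((4, 8), rng=rng)
    out = bb.forward(rng.normal(size=(2, 16, 16, 3)))
    assert out.shape == (2, 4, 4, 8)
    assert bb.out_channels == 8
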
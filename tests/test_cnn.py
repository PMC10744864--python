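"""Classifier architecture, gradients, training, and inference contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octmargin.cnn import (
    ArchConfig,
    TrainConfig,
    build_model,
    count_parameters,
    load_model,
    patches_to_arrays,
    predict_patches,
    save_model,
    select_epoch,
    train,
)
from octmargin.cnn import engine
from octmargin.patchgen import Patch

TINY = ArchConfig(conv_channels=(2, 3, 2, 2, 2), fc_sizes=(6, 4, 2),
                  input_shape=(36, 36, 1), dropout_rate=0.0)


def _tiny_patch_set(n_pos, n_neg, seed=0, h=36, w=36, blob=10):
    """Noise patches vs noise-plus-bright-square patches."""
    rng = np.random.default_rng(seed)
    patches = []
    for i in range(n_pos + n_neg):
        img = rng.normal(0.3, 0.08, size=(h, w))
        label = "negative"
        if i < n_pos:
            r, c = rng.integers(2, h - blob - 2), rng.integers(2, w - blob - 2)
            img[r : r + blob, c : c + blob] += 0.5
            label = "positive"
        img = np.clip(img, 0, 1).astype(np.float32)
        patches.append(Patch("S0", "M0", bscan_index=i, x_start=0, pixels=img, label=label))
    return patches


class TestParameterCount:
    def test_hand_computed_toy_count(self):
        arch = ArchConfig(conv_channels=(1, 1, 1, 1, 1), fc_sizes=(4, 2, 1),
                          input_shape=(36, 36, 1))
        # conv: 5 x (9*1*1 + 1) = 50; spatial 36->18->9->4->2->1, flatten = 1
        # fc: 1*4+4 + 4*2+2 + 2*1+1 = 8 + 10 + 3 = 21
        assert count_parameters(arch) == 71

    def test_default_meets_parameter_budget(self):
        n = count_parameters(ArchConfig())
        assert abs(n - 1_589_000) / 1_589_000 < 0.02

    @given(
        conv=st.lists(st.integers(1, 6), min_size=5, max_size=5),
        fc=st.tuples(st.integers(1, 12), st.integers(1, 8), st.sampled_from([1, 2])),
    )
    @settings(max_examples=15, deadline=None)
    def test_closed_form_equals_introspection(self, conv, fc):
        arch = ArchConfig(conv_channels=tuple(conv), fc_sizes=tuple(fc),
                          input_shape=(36, 36, 1))
        model = build_model(arch, seed=0)
        assert model.n_parameters() == count_parameters(arch)

    def test_widening_conv_increases_count(self):
        base = count_parameters(TINY)
        wider = ArchConfig(conv_channels=(4, 6, 4, 4, 4), fc_sizes=(6, 4, 2),
                           input_shape=(36, 36, 1))
        assert count_parameters(wider) > base

    def test_invalid_architectures_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(conv_channels=(8, 8, 16, 32))  # only 4 conv layers
        with pytest.raises(ValueError):
            ArchConfig(fc_sizes=(10, 5))  # only 2 fc layers
        with pytest.raises(ValueError):
            ArchConfig(fc_sizes=(10, 5, 3))  # 3 logits unsupported
        with pytest.raises(ValueError):
            ArchConfig(kernel_size=5)
        with pytest.raises(ValueError):
            # 36x36 pooled five times collapses to zero rows with extra pooling
            count_parameters(ArchConfig(input_shape=(20, 20, 1)))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Exact-gradient check in float64 (biases moved off the ReLU kink)."""
        model = build_model(TINY, seed=1)
        rng = np.random.default_rng(0)
        for layer in model.layers:
            if hasattr(layer, "W"):
                layer.W = layer.W.astype(np.float64)
                layer.dW = layer.dW.astype(np.float64)
                layer.b = (layer.b + 0.05 * rng.standard_normal(layer.b.shape)).astype(np.float64)
                layer.db = layer.db.astype(np.float64)
        x = rng.random((2, 36, 36, 1))
        y = np.array([0, 1])
        loss0, d = engine.softmax_cross_entropy(model.forward(x, train=True), y)
        model.backward(d.astype(np.float64))
        grads = [(p, g.copy()) for p, g in model.params()]
        for p, g in grads:
            for _ in range(6):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, orig = 1e-6, float(p[idx])
                p[idx] = orig + eps
                l1, _ = engine.softmax_cross_entropy(model.forward(x), y)
                p[idx] = orig - eps
                l2, _ = engine.softmax_cross_entropy(model.forward(x), y)
                p[idx] = orig
                numeric = (l1 - l2) / (2 * eps)
                assert abs(numeric - g[idx]) <= 1e-5 * max(1.0, abs(numeric))


class TestTraining:
    def test_one_epoch_selects_epoch_zero(self):
        model = build_model(TINY, seed=0)
        patches = _tiny_patch_set(8, 24)
        _, history = train(model, patches, patches[:8], TrainConfig(epochs=1, seed=0))
        assert history.selected_epoch == 0
        assert len(history.train_loss) == 1

    def test_same_seed_gives_identical_history(self):
        patches = _tiny_patch_set(8, 24)
        cfg = TrainConfig(epochs=3, seed=5)
        _, h1 = train(build_model(TINY, seed=0), patches, patches[:8], cfg)
        _, h2 = train(build_model(TINY, seed=0), patches, patches[:8], cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_single_class_training_data_rejected(self):
        patches = _tiny_patch_set(0, 16)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(TINY, seed=0), patches, patches[:4], TrainConfig(epochs=1))

    def test_learns_separable_toy_problem(self):
        arch = ArchConfig(conv_channels=(4, 4, 4, 4, 4), fc_sizes=(8, 4, 2),
                          input_shape=(36, 36, 1), dropout_rate=0.0)
        model = build_model(arch, seed=0)
        patches = _tiny_patch_set(40, 80, seed=3, blob=16)
        held_out = _tiny_patch_set(20, 40, seed=4, blob=16)
        best, history = train(
            model, patches, held_out,
            TrainConfig(epochs=10, seed=0, learning_rate=3e-3),
        )
        x, y = patches_to_arrays(held_out)
        probs = predict_patches(best, x)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, probs) > 0.9
        assert history.train_loss[-1] < history.train_loss[0]

    def test_checkpoint_is_from_selected_epoch(self):
        """Reloading the returned model must reproduce the selected epoch's
        validation loss, not the last epoch's."""
        model = build_model(TINY, seed=0)
        tr = _tiny_patch_set(20, 40, seed=3)
        va = _tiny_patch_set(10, 20, seed=4)
        best, history = train(model, tr, va, TrainConfig(epochs=5, seed=0))
        x, y = patches_to_arrays(va)
        logits = best.forward(x)
        loss, _ = engine.softmax_cross_entropy(logits, y)
        assert loss == pytest.approx(history.val_loss[history.selected_epoch], rel=1e-5)


class TestSelectEpoch:
    def test_minimum_loss_wins(self):
        assert select_epoch([0.5, 0.3, 0.4], [0.8, 0.8, 0.9]) == 1

    def test_tie_broken_by_accuracy_then_earlier(self):
        assert select_epoch([0.3, 0.3], [0.7, 0.9]) == 1
        assert select_epoch([0.3, 0.3], [0.9, 0.9]) == 0


class TestPrediction:
    def test_empty_patch_list(self):
        model = build_model(TINY, seed=0)
        assert predict_patches(model, []).shape == (0,)

    def test_batch_size_invariance(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((25, 36, 36, 1)).astype(np.float32)
        p1 = predict_patches(model, x, batch_size=1)
        p2 = predict_patches(model, x, batch_size=64)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_probabilities_in_unit_interval(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((10, 36, 36, 1)).astype(np.float32)
        p = predict_patches(model, x)
        assert ((p >= 0) & (p <= 1)).all()

    def test_softmax_head_complement_sums_to_one(self, rng):
        model = build_model(TINY, seed=0)
        x = rng.random((4, 36, 36, 1)).astype(np.float32)
        probs = engine.softmax(model.forward(x).astype(np.float64))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(TINY, seed=0)
        with pytest.raises(ValueError):
            predict_patches(model, rng.random((3, 20, 20, 1)).astype(np.float32))


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_model(TINY, seed=0)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    x = rng.random((5, 36, 36, 1)).astype(np.float32)
    np.testing.assert_array_equal(model.predict_proba(x), loaded.predict_proba(x))
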
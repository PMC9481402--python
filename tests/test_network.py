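"""Base-network construction, determinism, gradients, and tiny-scale training."""

import numpy as np
import pytest

from beatvote import _nn
from beatvote.dataset import AAMI_CLASSES, AamiClass
from beatvote.losses import FocalLossParams, focal_loss_and_grad
from beatvote.network import (
    ArchitectureSpec,
    ResidualConvNet,
    TrainingConfig,
    build_model,
    load_classifier,
    predict,
    save_classifier,
    train,
)
from beatvote.sampling import TrainingSet
from beatvote.segmentation import BeatSegment

TINY = ArchitectureSpec(kernel_size=5, filters=(3, 3, 3, 3, 3, 6, 6, 6, 6))


def _training_set(X, labels):
    segs = tuple(
        BeatSegment(x, lab, "toy", i) for i, (x, lab) in enumerate(zip(X, labels))
    )
    counts = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return TrainingSet(segments=segs, class_counts=counts)


def _toy_problem(n=200, length=64, seed=0):
    """Linearly separable two-class toy: class V has a large plateau."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 0.1, size=(n, length))
    labels = []
    for i in range(n):
        if i % 2:
            X[i, 20:44] += 2.0
            labels.append(AamiClass.V)
        else:
            labels.append(AamiClass.N)
    return X, labels


class TestArchitectureSpec:
    def test_default_matches_layer_plan(self):
        spec = ArchitectureSpec.default()
        assert spec.kernel_size == 17
        assert spec.filters == (20, 20, 20, 20, 20, 40, 40, 40, 40)
        assert spec.dropout_rate == 0.40
        assert spec.dropout_layers == frozenset(range(3, 10))
        assert spec.n_classes == 5

    def test_nine_layers_enforced(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(filters=(20, 20))


class TestBuildModel:
    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(16, ArchitectureSpec.default())

    def test_forward_on_zero_input_is_normalised_and_finite(self):
        model = build_model(508, ArchitectureSpec.scaled_down(), seed=0)
        probs = model.forward(np.zeros((2, 508)), training=False)
        assert probs.shape == (2, 5)
        assert np.all(np.isfinite(probs))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_outputs(self):
        x = np.random.default_rng(3).normal(size=(4, 128))
        a = build_model(128, TINY, seed=42).forward(x)
        b = build_model(128, TINY, seed=42).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_independent_of_seed(self):
        counts = {build_model(256, TINY, seed=s).n_parameters() for s in range(3)}
        assert len(counts) == 1

    def test_eval_forward_deterministic_despite_dropout(self):
        model = build_model(128, TINY, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 128))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Full-topology gradient check in float64 on a miniature spec."""
        spec = ArchitectureSpec(
            kernel_size=5, filters=(3, 3, 3, 3, 3, 6, 6, 6, 6), dropout_rate=0.0
        )
        net = ResidualConvNet(24, spec, seed=1, dtype=np.float64)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 24))
        y = np.array([0, 2, 1, 4])
        params = FocalLossParams()

        def loss_at():
            probs = net.forward(X, training=True)
            return focal_loss_and_grad(probs, y, params)[0]

        probs = net.forward(X, training=True)
        _, dlogits = focal_loss_and_grad(probs, y, params)
        net.zero_grad()
        net.backward(dlogits)
        eps = 1e-6
        checked = 0
        for par, grad in net.param_pairs():
            flat, gflat = par.ravel(), grad.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_at()
                flat[i] = orig - eps
                lm = loss_at()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(numeric, abs=2e-6)
                checked += 1
        assert checked > 50


class TestTraining:
    def test_separable_toy_reaches_high_accuracy(self):
        X, labels = _toy_problem()
        ts = _training_set(X, labels)
        model = build_model(64, TINY, seed=1)
        clf = train(
            model,
            ts,
            FocalLossParams(),
            TrainingConfig(epochs=20, batch_size=32, val_fraction=0.0, seed=0),
        )
        Xh, lh = _toy_problem(n=80, seed=99)
        probs = clf.predict_proba(Xh)
        pred = [AAMI_CLASSES[j] for j in probs.argmax(axis=1)]
        acc = np.mean([p is t for p, t in zip(pred, lh)])
        assert acc >= 0.9

    def test_single_item_loss_decreases_after_one_epoch(self):
        x = np.random.default_rng(5).normal(size=(1, 64))
        ts = _training_set(x, [AamiClass.S])
        model = build_model(64, TINY, seed=2)
        params = FocalLossParams()
        before = focal_loss_and_grad(
            model.forward(x, training=False), np.array([1]), params
        )[0]
        clf = train(
            model, ts, params,
            TrainingConfig(epochs=1, batch_size=1, val_fraction=0.0, seed=0),
        )
        after = focal_loss_and_grad(
            clf.model.forward(x, training=False), np.array([1]), params
        )[0]
        assert after < before

    def test_mixed_segment_lengths_rejected(self):
        segs = (
            BeatSegment(np.zeros(64), AamiClass.N, "a", 0),
            BeatSegment(np.zeros(32), AamiClass.N, "a", 1),
        )
        ts = TrainingSet(segments=segs, class_counts={AamiClass.N: 2})
        with pytest.raises(ValueError, match="length"):
            train(build_model(64, TINY, seed=0), ts)

    def test_history_records_epoch_losses(self):
        X, labels = _toy_problem(n=40)
        clf = train(
            build_model(64, TINY, seed=0),
            _training_set(X, labels),
            FocalLossParams(),
            TrainingConfig(epochs=3, batch_size=16, val_fraction=0.0, seed=0),
        )
        assert [h["epoch"] for h in clf.history] == [0, 1, 2]
        assert all(np.isfinite(h["train_loss"]) for h in clf.history)


class TestPredict:
    def _trained(self):
        X, labels = _toy_problem(n=60)
        return train(
            build_model(64, TINY, seed=0),
            _training_set(X, labels),
            FocalLossParams(),
            TrainingConfig(epochs=2, batch_size=16, val_fraction=0.0, seed=0),
        )

    def test_probabilities_sum_to_one(self):
        clf = self._trained()
        seg = BeatSegment(np.zeros(64), AamiClass.N, "x", 0)
        probs = predict(clf, seg)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-6)

    def test_length_mismatch_rejected(self):
        clf = self._trained()
        with pytest.raises(ValueError, match="length"):
            predict(clf, BeatSegment(np.zeros(32), AamiClass.N, "x", 0))

    def test_save_load_round_trip_preserves_outputs(self, tmp_path):
        clf = self._trained()
        x = np.random.default_rng(1).normal(size=(5, 64))
        save_classifier(clf, tmp_path / "member1")
        back = load_classifier(tmp_path / "member1")
        np.testing.assert_allclose(
            clf.predict_proba(x), back.predict_proba(x), atol=1e-7
        )


class TestSoftmax:
    def test_shift_invariance_of_argmax(self):
        z = np.array([[0.2, 1.5, -0.3, 0.0, 0.9]])
        a = _nn.softmax(z)
        b = _nn.softmax(z + 100.0)
        np.testing.assert_allclose(a, b, atol=1e-12)
        assert a.argmax() == b.argmax()
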
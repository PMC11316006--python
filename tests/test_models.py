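"""Classifier/regressor contracts, channel mapping, network internals."""

import numpy as np
import pytest

from emgsleeve import models
from emgsleeve._mlp import MLP, one_cycle_lr
from emgsleeve.errors import ConfigurationError, FittingError
from emgsleeve.models import (
    ClassifierSpec,
    RegressorSpec,
    build_channel_map,
    map_channels,
    predict_proba,
    train_classifier,
    train_regressor,
)
from emgsleeve.simdata import SleeveLayout


def _separable(rng, n=120, d=8):
    x = rng.normal(size=(n, d))
    y = np.where(x[:, 0] + x[:, 1] > 0, "pos", "neg")
    x[y == "pos"] += 3.0
    return x, y


class TestClassifier:
    @pytest.mark.parametrize("kind", ["logistic_regression", "extra_trees", "nn"])
    def test_separable_data_fits_perfectly(self, rng, kind):
        x, y = _separable(rng)
        spec = ClassifierSpec(kind=kind, hidden=(32, 16), epochs=60)
        model = train_classifier(spec, x, y, seed=0)
        assert np.mean(model.predict(x) == y) == 1.0

    def test_probabilities_normalized(self, rng):
        x, y = _separable(rng)
        model = train_classifier(ClassifierSpec(hidden=(16, 8), epochs=5), x, y, seed=0)
        p = predict_proba(model, x)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_rows_identical_probabilities(self, rng):
        x, y = _separable(rng)
        model = train_classifier(ClassifierSpec(hidden=(16, 8), epochs=5), x, y, seed=0)
        p = predict_proba(model, np.vstack([x[:1], x[:1]]))
        assert np.array_equal(p[0], p[1])

    def test_argmax_matches_predict(self, rng):
        x, y = _separable(rng)
        model = train_classifier(ClassifierSpec(hidden=(16, 8), epochs=5), x, y, seed=0)
        p = predict_proba(model, x)
        assert np.array_equal(model.classes_[p.argmax(axis=1)], model.predict(x))

    def test_nn_deterministic_given_seed(self, rng):
        x, y = _separable(rng)
        spec = ClassifierSpec(hidden=(16, 8), epochs=5)
        p1 = predict_proba(train_classifier(spec, x, y, seed=3), x)
        p2 = predict_proba(train_classifier(spec, x, y, seed=3), x)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(10, 3))
        with pytest.raises(FittingError):
            train_classifier(ClassifierSpec(), x, np.array(["a"] * 10), seed=0)


class TestRegressor:
    def test_ridge_recovers_linear_map(self, rng):
        x = rng.normal(size=(300, 10))
        w = rng.normal(size=(10, 4))
        y = x @ w
        model = train_regressor(RegressorSpec(kind="ridge"), x[:200], y[:200], ("a", "b", "c", "d"), 0)
        from sklearn.metrics import r2_score

        assert r2_score(y[200:], model.predict(x[200:])) > 0.99

    def test_kernel_ridge_constant_target_ok(self, rng):
        x = rng.normal(size=(50, 5))
        y = np.column_stack([np.ones(50), rng.normal(size=50)])
        model = train_regressor(
            RegressorSpec(kind="laplacian_kernel_ridge"), x, y, ("c", "v"), 0
        )
        assert np.all(np.isfinite(model.predict(x)))

    def test_nn_outputs_clipped_to_training_range(self, rng):
        x = rng.normal(size=(100, 6))
        y = rng.uniform(10, 20, size=(100, 3))
        model = train_regressor(
            RegressorSpec(hidden=(16, 8), epochs=5), x, y, ("a", "b", "c"), 0
        )
        probe = model.predict(rng.normal(size=(5, 6)) * 1000.0)
        assert np.all(probe >= y.min(axis=0) - 1e-9)
        assert np.all(probe <= y.max(axis=0) + 1e-9)


class TestChannelMap:
    def test_medium_to_medium_identity(self, rng):
        medium = SleeveLayout.from_size("medium")
        rms = rng.random((15, 70))
        assert np.array_equal(map_channels(rms, medium, medium), rms)

    def test_large_maps_to_seventy(self, rng):
        out = map_channels(rng.random((10, 75)), SleeveLayout.from_size("large"))
        assert out.shape == (10, 70)

    def test_small_maps_with_duplication(self):
        cmap = build_channel_map(SleeveLayout.from_size("small"))
        assert len(cmap.assignment) == 70
        assert cmap.n_duplicated >= 70 - 59  # pigeonhole

    def test_channel_count_mismatch_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            map_channels(rng.random((10, 59)), SleeveLayout.from_size("large"))


class TestMLPInternals:
    def test_one_cycle_rises_then_falls(self):
        lrs = [one_cycle_lr(s, 100, 1e-3) for s in range(100)]
        peak = int(np.argmax(lrs))
        assert 0 < peak < 99
        assert all(a <= b + 1e-12 for a, b in zip(lrs[:peak], lrs[1:peak + 1]))
        assert all(a >= b - 1e-12 for a, b in zip(lrs[peak:], lrs[peak + 1:]))
        assert lrs[-1] < lrs[0]

    def test_recorded_schedule_one_cycle(self, rng):
        x, y = _separable(rng)
        model = train_classifier(ClassifierSpec(hidden=(8, 4), epochs=4), x, y, seed=0)
        lr = np.array(model.curves[0].lr)
        peak = int(lr.argmax())
        assert 0 < peak < len(lr) - 1

    def test_gradients_match_numeric(self):
        # finite-difference check of the full backward pass (no dropout)
        rng = np.random.default_rng(0)
        net = MLP(4, (5,), 3, dropout=0.0, seed=1, task="classify")
        x = rng.normal(size=(6, 4)).astype(np.float32)
        y = np.array([0, 1, 2, 0, 1, 2])

        def loss_at():
            out = net._forward_train(x)
            return net._loss_grad(out, y)[0]

        out = net._forward_train(x)
        loss, g = net._loss_grad(out, y)
        net._backward(g)
        w = net.linears[0].w
        analytic = net.linears[0].gw.copy()
        eps = 1e-3
        for idx in [(0, 0), (2, 3), (3, 1)]:
            orig = w[idx]
            w[idx] = orig + eps
            lp = loss_at()
            w[idx] = orig - eps
            lm = loss_at()
            w[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert np.isclose(numeric, analytic[idx], rtol=0.15, atol=1e-4)

    def test_label_smoothing_targets_sum_to_one(self):
        net = MLP(3, (4,), 5, dropout=0.0, seed=0, task="classify", label_smoothing=0.1)
        out = np.zeros((2, 5), dtype=np.float32)
        loss, g = net._loss_grad(out, np.array([1, 3]))
        # gradient of -sum(q log p) at uniform p has zero row sums when q sums to 1
        assert np.allclose(g.sum(axis=1), 0.0, atol=1e-7)


class TestPretrainFinetune:
    def test_finetune_on_same_distribution_not_worse(self, rng):
        x, y = _separable(rng, n=200)
        spec = ClassifierSpec(hidden=(16, 8), epochs=60, finetune_epochs=10)
        bundle = models.pretrain_finetune(spec, [(x, y)], (x, y), seed=0)
        acc = np.mean(bundle.model.predict(models._scale_rows(x, bundle.scaler)) == y)
        assert acc == 1.0  # separable either way; fine-tuning must not break it

    def test_class_mismatch_reinitializes_head(self, rng):
        x, y = _separable(rng, n=150)
        x2 = rng.normal(size=(90, 8))
        y2 = np.array(["a", "b", "c"] * 30)
        spec = ClassifierSpec(hidden=(16, 8), epochs=5, finetune_epochs=5)
        bundle = models.pretrain_finetune(spec, [(x, y)], (x2, y2), seed=0)
        assert list(bundle.model.classes_) == ["a", "b", "c"]
        assert bundle.model.predict_proba(np.zeros((1, 8))).shape == (1, 3)
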
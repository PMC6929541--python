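"""The convolutional classifier: geometry, gradients, training, persistence."""

import numpy as np
import pytest

import dtimage.cnn as cnn
from dtimage.cnn import (
    GeometryError,
    ModelConfig,
    TrainedModel,
    TrainingDivergedError,
    TrainingError,
    _softmax_xent,
    build_model,
    train,
)

TINY = dict(conv_filters=(2, 3, 4), fc_units=5, kernel_size=3)


def separable_images(rng, n=400, side=10):
    """Images where the label controls a bright patch: trivially separable."""
    labels = rng.integers(2, size=n)
    imgs = (rng.standard_normal((n, side, side)) * 0.1).astype(np.float32)
    imgs[labels == 1, 2:5, 2:5] += 1.0
    return imgs, labels


class TestBuild:
    def test_smoke_forward_two_finite_scores(self):
        net = build_model(ModelConfig(seed=0), image_side=28)
        logits = net.forward(np.zeros((1, 28, 28), dtype=np.float32))
        assert logits.shape == (1, 2)
        assert np.isfinite(logits).all()

    def test_batch_norm_flag_recorded_and_disabled(self):
        net = build_model(ModelConfig(batch_norm=False, seed=0), image_side=28)
        assert net.bn is None
        assert net.config.batch_norm is False

    def test_small_side_constructs_with_valid_pooling_plan(self):
        net = build_model(ModelConfig(**TINY, seed=0), image_side=10)
        assert net.map_plan == [10, 5, 2]

    def test_collapsing_geometry_is_an_error_listing_sides(self):
        with pytest.raises(GeometryError, match=r"\[3, 1, 0\]"):
            build_model(ModelConfig(**TINY, seed=0), image_side=3)

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)


class TestGradients:
    """Backpropagation against a finite-difference oracle."""

    @staticmethod
    def _to_float64(net):
        for layer in net._layers_with_params:
            for p in layer.params:
                setattr(layer, p, getattr(layer, p).astype(np.float64))

    @pytest.mark.parametrize("batch_norm", [True, False])
    def test_parameter_gradients_match_finite_differences(self, rng, batch_norm):
        config = ModelConfig(**TINY, batch_norm=batch_norm, dropout_rate=0.0, seed=1)
        net = build_model(config, image_side=8)
        self._to_float64(net)
        x = rng.standard_normal((6, 8, 8))
        y = rng.integers(2, size=6)

        def loss_fn():
            logits = net.forward(x, training=True)
            loss, dlogits, _ = _softmax_xent(logits, y)
            return loss, dlogits

        loss, dlogits = loss_fn()
        net.backward(dlogits)
        eps = 1e-6
        for layer in net._layers_with_params:
            for pname in layer.params:
                param = getattr(layer, pname)
                grad = getattr(layer, "d" + pname)
                flat = param.reshape(-1)
                for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up, _ = loss_fn()
                    flat[idx] = orig - eps
                    dn, _ = loss_fn()
                    flat[idx] = orig
                    fd = (up - dn) / (2 * eps)
                    assert grad.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTrain:
    @pytest.mark.parametrize("optimizer", ["sgd", "adam"])
    def test_separable_data_reaches_high_training_accuracy(self, rng, optimizer):
        imgs, labels = separable_images(rng)
        config = ModelConfig(
            conv_filters=(8, 16, 32), fc_units=32, batch_size=64, optimizer=optimizer,
            max_iterations=500, log_every=50, seed=1,
        )
        model = train(build_model(config, 10), imgs, labels, config)
        acc = ((model.score(imgs) >= 0.5).astype(int) == labels).mean()
        assert acc >= 0.99

    def test_loss_trend_decreases_on_separable_data(self, rng):
        imgs, labels = separable_images(rng)
        config = ModelConfig(
            conv_filters=(4, 8, 16), fc_units=16, batch_size=64,
            max_iterations=300, log_every=20, seed=2,
        )
        model = train(build_model(config, 10), imgs, labels, config)
        losses = [l for _, l in model.training_log]
        first_third = np.mean(losses[: len(losses) // 3])
        last_third = np.mean(losses[-(len(losses) // 3):])
        assert last_third < first_third

    def test_same_seed_same_data_identical_weights(self, rng):
        imgs, labels = separable_images(rng, n=120)
        config = ModelConfig(**TINY, batch_size=32, max_iterations=60, seed=7)
        m1 = train(build_model(config, 10), imgs, labels, config)
        m2 = train(build_model(config, 10), imgs, labels, config)
        assert m1.training_log[-1] == m2.training_log[-1]
        for key, arr in m1.net.state_arrays().items():
            np.testing.assert_array_equal(arr, m2.net.state_arrays()[key])

    def test_huge_learning_rate_aborts_with_diagnostic(self, rng):
        imgs, labels = separable_images(rng, n=120)
        config = ModelConfig(
            **TINY, batch_norm=False, batch_size=32, max_iterations=200,
            learning_rate=1e12, seed=0,
        )
        with pytest.raises(TrainingDivergedError, match="learning"):
            train(build_model(config, 10), imgs * 100, labels, config)

    def test_single_class_input_is_an_error(self, rng):
        imgs = rng.standard_normal((20, 10, 10)).astype(np.float32)
        config = ModelConfig(**TINY, seed=0)
        with pytest.raises(TrainingError, match="single class"):
            train(build_model(config, 10), imgs, np.ones(20, dtype=int), config)

    def test_with_and_without_bn_both_complete_on_scaled_data(self, rng):
        imgs, labels = separable_images(rng, n=200)
        for bn in (True, False):
            config = ModelConfig(
                **TINY, batch_norm=bn, batch_size=32, max_iterations=100, seed=3
            )
            model = train(build_model(config, 10), imgs, labels, config)
            assert np.isfinite(model.training_log[-1][1])


class TestScore:
    @pytest.fixture
    def trained(self, rng):
        imgs, labels = separable_images(rng, n=150)
        config = ModelConfig(**TINY, batch_size=32, max_iterations=80, seed=4)
        return train(build_model(config, 10), imgs, labels, config), imgs

    def test_probabilities_complement_to_one(self, trained):
        model, imgs = trained
        logits = model.net.forward(imgs[:16].astype(np.float32), training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(model.score(imgs[:16]), probs[:, 1], atol=1e-6)

    def test_batch_equals_one_by_one(self, trained):
        model, imgs = trained
        batch = model.score(imgs[:20])
        singles = np.array([model.score(imgs[i : i + 1])[0] for i in range(20)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_scoring_is_deterministic(self, trained):
        model, imgs = trained
        np.testing.assert_array_equal(model.score(imgs[:32]), model.score(imgs[:32]))

    def test_geometry_mismatch_is_an_error(self, trained):
        model, _ = trained
        with pytest.raises(GeometryError):
            model.score(np.zeros((2, 12, 12)))

    def test_save_load_round_trip_scores_identical(self, trained, tmp_path):
        model, imgs = trained
        path = tmp_path / "model.ckpt"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_allclose(back.score(imgs[:32]), model.score(imgs[:32]), atol=1e-7)
        assert back.class_order == ("negative", "positive")

    def test_version_mismatch_fails_loudly(self, trained, tmp_path, monkeypatch):
        model, _ = trained
        path = tmp_path / "model.ckpt"
        monkeypatch.setattr(cnn, "CHECKPOINT_FORMAT_VERSION", 99)
        model.save(path)
        monkeypatch.undo()
        with pytest.raises(ValueError, match="format"):
            TrainedModel.load(path)
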
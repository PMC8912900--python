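"""Training loop: balance, augmentation, determinism, learning."""

import numpy as np
import pytest

from nervedetect.model import build_model, save_model, load_model
from nervedetect.model import ModelConfig
from nervedetect.preprocessing import TrainingSample
from nervedetect.training import (
    TrainConfig,
    augment,
    balanced_batch_generator,
    train,
)


def make_sample(label: str, seed: int, P: int = 32) -> TrainingSample:
    rng = np.random.default_rng(seed)
    if label == "positive":
        patch = np.full((P, P, 3), 240, dtype=np.uint8)
        mask = np.zeros((P, P), dtype=bool)
        y, x = rng.integers(4, P - 12, 2)
        patch[y : y + 8, x : x + 8] = (150, 92, 43)
        mask[y : y + 8, x : x + 8] = True
    else:
        patch = rng.integers(200, 256, (P, P, 3)).astype(np.uint8)
        mask = np.zeros((P, P), dtype=bool)
    return TrainingSample(image_patch=patch, label_mask=mask, class_label=label)


@pytest.fixture()
def pools():
    pos = [make_sample("positive", i) for i in range(7)]
    neg = [make_sample("negative", 100 + i) for i in range(5)]
    return pos, neg


class TestBalancedBatches:
    def test_every_batch_is_balanced(self, pools):
        pos, neg = pools
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        gen = balanced_batch_generator(pos, neg, cfg)
        for _ in range(50):
            x, y = next(gen)
            assert x.shape == (8, 32, 32, 3)
            assert y.shape == (8, 32, 32, 1)
            # the first half of each batch is positive, second half negative
            assert all(y[i].any() for i in range(4))
            assert not y[4:].any()

    def test_same_seed_same_stream(self, pools):
        pos, neg = pools
        cfg = TrainConfig(epochs=1, batch_size=4, seed=9)
        a = balanced_batch_generator(pos, neg, cfg)
        b = balanced_batch_generator(pos, neg, cfg)
        for _ in range(20):
            xa, ya = next(a)
            xb, yb = next(b)
            np.testing.assert_array_equal(xa, xb)
            np.testing.assert_array_equal(ya, yb)

    def test_empty_pool_rejected(self, pools):
        pos, _ = pools
        with pytest.raises(ValueError, match="non-empty"):
            next(balanced_batch_generator(pos, [], TrainConfig(epochs=1)))

    def test_odd_batch_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            TrainConfig(batch_size=7)


class TestAugment:
    def test_negative_label_stays_all_false(self, rng):
        img = rng.random((32, 32, 3)).astype(np.float32)
        mask = np.zeros((32, 32), dtype=np.float32)
        for _ in range(20):
            _, out = augment(img, mask, rng)
            assert not out.any()

    def test_geometry_applied_jointly(self, rng):
        """The mask tracks the image through every transform: a marked pixel
        block stays colocated."""
        img = np.zeros((32, 32, 3), dtype=np.float32)
        mask = np.zeros((32, 32), dtype=np.float32)
        img[10:14, 20:24] = 1.0
        mask[10:14, 20:24] = 1.0
        for _ in range(20):
            ai, am = augment(img, mask, rng)
            np.testing.assert_array_equal(ai[:, :, 0] > 0.5, am > 0.5)

    def test_shapes_preserved(self, rng):
        img = rng.random((64, 64, 3)).astype(np.float32)
        mask = rng.random((64, 64)).astype(np.float32)
        ai, am = augment(img, mask, rng)
        assert ai.shape == img.shape and am.shape == mask.shape


class TestTrain:
    def test_loss_decreases_on_learnable_set(self, pools):
        pos, neg = pools
        model = build_model(ModelConfig(input_size=(32, 32), depth=2, filters_per_level=(4, 8, 16), seed=0))
        cfg = TrainConfig(learning_rate=1e-3, epochs=8, batch_size=4, seed=0)
        history = train(model, pos + neg, cfg)
        assert history.loss[-1] < history.loss[0]

    def test_training_deterministic_under_seed(self, pools):
        pos, neg = pools
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=4, seed=3)
        results = []
        for _ in range(2):
            model = build_model(ModelConfig(input_size=(32, 32), depth=2, filters_per_level=(4, 8, 16), seed=1))
            train(model, pos + neg, cfg)
            results.append([p.data.copy() for p in model.parameters()])
        for a, b in zip(*results):
            np.testing.assert_array_equal(a, b)

    def test_dataset_order_irrelevant(self, pools):
        pos, neg = pools
        cfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=4, seed=3)
        weights = []
        for ordering in (pos + neg, list(reversed(pos)) + list(reversed(neg))):
            model = build_model(ModelConfig(input_size=(32, 32), depth=2, filters_per_level=(4, 8, 16), seed=1))
            train(model, ordering, cfg)
            weights.append([p.data.copy() for p in model.parameters()])
        # the generator indexes pools by position, so reversing a pool is a
        # relabelling of identical content only when samples coincide; here
        # we assert invariance to concatenation order of the two pools
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_requires_both_classes(self, pools):
        pos, _ = pools
        model = build_model(ModelConfig(input_size=(32, 32), depth=2, filters_per_level=(4, 8, 16), seed=0))
        with pytest.raises(ValueError, match="non-empty"):
            train(model, pos, TrainConfig(epochs=1))


class TestTrainedTinyModel:
    """Checks on the session-trained tiny network (the expensive fixture)."""

    def test_loss_curve_descends(self, tiny_trained):
        _, history = tiny_trained
        assert history.loss[-1] < 0.5 * history.loss[0]

    def test_heldout_patch_classification_accuracy(self, tiny_trained):
        """>=0.9 patch-level class accuracy on samples from unseen slides."""
        from nervedetect.experiments import benchmark_slide_spec, TINY_PATCH
        from nervedetect.preprocessing import build_training_samples
        from nervedetect.synthetic import generate_slide

        model, _ = tiny_trained
        samples = []
        for seed in (300, 301, 302):
            s = generate_slide(benchmark_slide_spec(seed))
            samples += build_training_samples(
                s.image, s.expert_annotations, s.negative_regions, P=TINY_PATCH
            )
        x = np.stack([t.image_patch for t in samples]).astype(np.float32) / 255.0
        truth = np.array([t.class_label == "positive" for t in samples])
        _, cls, _ = model.predict(x)
        assert ((cls > 0.5) == truth).mean() >= 0.9

    def test_heldout_pixel_accuracy(self, tiny_trained):
        """>=0.95 pixel accuracy of the gated output on unseen samples."""
        from nervedetect.experiments import benchmark_slide_spec, TINY_PATCH
        from nervedetect.preprocessing import build_training_samples
        from nervedetect.synthetic import generate_slide

        model, _ = tiny_trained
        s = generate_slide(benchmark_slide_spec(310))
        samples = build_training_samples(
            s.image, s.expert_annotations, s.negative_regions, P=TINY_PATCH
        )
        x = np.stack([t.image_patch for t in samples]).astype(np.float32) / 255.0
        y = np.stack([t.label_mask for t in samples])
        _, _, gated = model.predict(x)
        assert ((gated > 0.5) == y).mean() >= 0.95

    def test_save_load_preserves_inference(self, tiny_trained, tmp_path, rng):
        model, _ = tiny_trained
        x = rng.random((2, 64, 64, 3)).astype(np.float32)
        before = model.predict(x)
        save_model(model, tmp_path / "m.npz")
        after = load_model(tmp_path / "m.npz").predict(x)
        for u, v in zip(before, after):
            np.testing.assert_array_equal(u, v)
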
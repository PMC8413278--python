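import numpy as np
import pytest

from cytophase.classifier import (
    CLASS_ORDER,
    LabeledDataset,
    TrainConfig,
    balance_classes,
    build_model,
    load_model,
    predict,
    preprocess_crop,
    save_model,
    split_train_val,
    train_classifier,
)
from cytophase.nn import MaxPool2D
from cytophase.phase_optics import Condition
from cytophase.segmentation import CellCrop
from cytophase.synthetic_data import generate_labeled_dataset


def tiny_crop(cls: str, i: int) -> CellCrop:
    """A minimal 2x2 labelled crop for count/split bookkeeping tests."""
    return CellCrop(
        pixels=np.zeros((2, 2), np.float32),
        centroid_rc=(1, 1),
        area_px=100,
        capture_id=f"cap-{cls}",
        condition=Condition(cls),
        crop_id=f"{cls}-{i:05d}",
    )


def counts_dataset(n_alive, n_apo, n_necro) -> LabeledDataset:
    crops = [tiny_crop("alive", i) for i in range(n_alive)]
    crops += [tiny_crop("apoptosis", i) for i in range(n_apo)]
    crops += [tiny_crop("necroptosis", i) for i in range(n_necro)]
    return LabeledDataset(crops=crops)


@pytest.fixture(scope="module")
def separable_dataset():
    return generate_labeled_dataset(200, seed=77)


class TestBalance:
    def test_protocol_counts_balance_to_smallest_class(self):
        ds = counts_dataset(8475, 19339, 10728)
        balanced = balance_classes(ds, seed=0)
        assert balanced.class_counts == {"alive": 8475, "apoptosis": 8475, "necroptosis": 8475}

    def test_already_balanced_returns_unchanged(self):
        ds = counts_dataset(10, 10, 10)
        assert balance_classes(ds, seed=1) is ds

    def test_small_counts_subset_property(self):
        ds = counts_dataset(3, 7, 5)
        balanced = balance_classes(ds, seed=2)
        assert balanced.class_counts == {"alive": 3, "apoptosis": 3, "necroptosis": 3}
        assert {c.crop_id for c in balanced.crops} <= {c.crop_id for c in ds.crops}

    def test_idempotent(self):
        ds = counts_dataset(4, 9, 6)
        once = balance_classes(ds, seed=3)
        twice = balance_classes(once, seed=3)
        assert [c.crop_id for c in twice.crops] == [c.crop_id for c in once.crops]

    def test_input_order_invariance(self):
        ds = counts_dataset(5, 9, 7)
        shuffled = LabeledDataset(crops=list(reversed(ds.crops)))
        a = {c.crop_id for c in balance_classes(ds, seed=4).crops}
        b = {c.crop_id for c in balance_classes(shuffled, seed=4).crops}
        assert a == b

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no crops"):
            balance_classes(counts_dataset(5, 0, 5), seed=0)


class TestSplit:
    def test_protocol_split_arithmetic(self):
        # floor(8475 * 0.2) = 1695 validation, 6780 training per class
        ds = counts_dataset(8475, 8475, 8475)
        train, val = split_train_val(ds, 0.20, seed=0)
        assert train.class_counts == {c: 6780 for c in CLASS_ORDER}
        assert val.class_counts == {c: 1695 for c in CLASS_ORDER}

    def test_disjoint_and_exhaustive(self):
        ds = counts_dataset(20, 20, 20)
        train, val = split_train_val(ds, 0.25, seed=5)
        train_ids = {c.crop_id for c in train.crops}
        val_ids = {c.crop_id for c in val.crops}
        assert not (train_ids & val_ids)
        assert train_ids | val_ids == {c.crop_id for c in ds.crops}

    def test_same_seed_reproduces_split(self):
        ds = counts_dataset(30, 30, 30)
        a = split_train_val(ds, 0.2, seed=6)
        b = split_train_val(ds, 0.2, seed=6)
        assert [c.crop_id for c in a[0].crops] == [c.crop_id for c in b[0].crops]
        assert [c.crop_id for c in a[1].crops] == [c.crop_id for c in b[1].crops]

    def test_empty_validation_split_rejected(self):
        ds = counts_dataset(4, 4, 4)
        with pytest.raises(ValueError, match="cannot be split"):
            split_train_val(ds, 0.2, seed=0)


class TestPreprocess:
    def test_resize_to_vgg_input(self, separable_dataset):
        out = preprocess_crop(separable_dataset.crops[0], (224, 224))
        assert out.shape == (224, 224, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_constant_crop_maps_to_zeros(self):
        crop = tiny_crop("alive", 0)
        out = preprocess_crop(crop, (66, 66))
        assert np.all(out == 0.0)
        assert out.shape == (66, 66, 3)

    def test_three_channels_identical(self, separable_dataset):
        out = preprocess_crop(separable_dataset.crops[3], (66, 66))
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 1])
        np.testing.assert_array_equal(out[:, :, 0], out[:, :, 2])


class TestArchitecture:
    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            build_model("resnet50")

    def test_small_cnn_probabilities_sum_to_one(self, separable_dataset):
        model = build_model("small_cnn", seed=0)
        probs, labels = predict(model, separable_dataset.crops[:8])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (8, 3)
        assert set(labels) <= set(CLASS_ORDER)

    def test_vgg19_final_feature_map_is_7x7x512(self, vgg_model):
        x = np.random.default_rng(0).random((1, 224, 224, 3), dtype=np.float32)
        fm = vgg_model.conv_feature_map(x)
        assert fm.shape == (1, 7, 7, 512)
        assert fm.reshape(1, -1).shape[1] == 7 * 7 * 512 == 25088

    def test_vgg19_pools_halve_spatial_size(self, vgg_model):
        x = np.random.default_rng(1).random((1, 224, 224, 3), dtype=np.float32)
        sizes = []
        h = x
        for layer in vgg_model.network.layers[: vgg_model.last_pool_index + 1]:
            h = layer.forward(h)
            if isinstance(layer, MaxPool2D):
                sizes.append(h.shape[1])
        assert sizes == [112, 56, 28, 14, 7]

    def test_head_is_fc64_relu_fc3(self, separable_dataset):
        model = build_model("small_cnn", seed=0)
        head = model.head_layers
        assert head[0].W.shape[1] == 64
        assert type(head[1]).__name__ == "ReLU"
        assert head[2].W.shape == (64, 3)


class TestTraining:
    def test_separable_classes_reach_high_validation_accuracy(self, separable_dataset):
        train, val = split_train_val(separable_dataset, 0.2, seed=0)
        model = build_model("small_cnn", seed=0)
        model, history = train_classifier(model, train, val, TrainConfig(seed=0, epochs=10))
        assert max(h["val_acc"] for h in history) >= 0.90
        # loss decreases on average over training
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_same_seed_gives_identical_result(self, separable_dataset):
        train, val = split_train_val(separable_dataset, 0.2, seed=1)
        accs, weights = [], []
        for _ in range(2):
            model = build_model("small_cnn", seed=2)
            model, history = train_classifier(model, train, val, TrainConfig(seed=2, epochs=3))
            accs.append(history[-1]["val_acc"])
            weights.append(model.network.get_weights())
        assert accs[0] == accs[1]
        for w1, w2 in zip(*weights):
            np.testing.assert_array_equal(w1, w2)

    def test_single_class_training_rejected(self, separable_dataset):
        groups = separable_dataset.by_class()
        ds = LabeledDataset(crops=groups["alive"][:20])
        model = build_model("small_cnn", seed=0)
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(model, ds, ds, TrainConfig(epochs=1))

    def test_empty_training_set_rejected(self):
        model = build_model("small_cnn", seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_classifier(model, LabeledDataset(crops=[]), LabeledDataset(crops=[]), TrainConfig())

    def test_planted_class_recovery_on_probes(self, separable_dataset):
        train, val = split_train_val(separable_dataset, 0.2, seed=0)
        model = build_model("small_cnn", seed=0)
        model, _ = train_classifier(model, train, val, TrainConfig(seed=0, epochs=10))
        probes = generate_labeled_dataset(40, seed=555)
        _, labels = predict(model, probes.crops)
        for cls in CLASS_ORDER:
            mask = probes.labels == cls
            assert np.mean(labels[mask] == cls) >= 0.90


class TestPredict:
    def test_batch_equals_per_crop_prediction(self, separable_dataset):
        model = build_model("small_cnn", seed=0)
        crops = separable_dataset.crops[:6]
        batch_probs, _ = predict(model, crops)
        single = np.vstack([predict(model, [c])[0] for c in crops])
        np.testing.assert_allclose(batch_probs, single, atol=1e-6)

    def test_wrong_crop_shape_rejected(self, separable_dataset):
        model = build_model("small_cnn", seed=0)
        with pytest.raises(ValueError):
            predict(model, [np.zeros((66, 66, 3), np.float32)])

    def test_save_load_preserves_predictions(self, tmp_path, separable_dataset):
        model = build_model("small_cnn", seed=9)
        crops = separable_dataset.crops[:5]
        before, _ = predict(model, crops)
        save_model(model, tmp_path / "clf")
        after, _ = predict(load_model(tmp_path / "clf"), crops)
        np.testing.assert_array_equal(before, after)
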
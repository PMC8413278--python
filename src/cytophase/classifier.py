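"""Dataset balancing, preprocessing, and the three-class cell-death network.

The classifier follows the transfer-learning recipe: take a VGG-19-style
convolutional backbone, remove its final classification stack, and attach a
new head — fully-connected 64 → ReLU → fully-connected 3 → softmax — so the
network emits (alive, apoptosis, necroptosis) probabilities per crop.

Two backbones exist:

* ``vgg19_full`` — the full VGG-19 arrangement on 224×224×3 input
  (16 conv layers in 5 blocks, 2×2 max-pools halving the spatial size,
  ending at a 7×7×512 feature map, then FC-4096 / ReLU / FC-4096 / ReLU).
  The new head attaches after the penultimate FC-4096 activation, i.e. the
  original FC-1000 / softmax / classification-output stack — the "last
  three layers" — is deleted. Weights are seeded-random unless loaded; no
  pretrained weights ship with the package.
* ``small_cnn`` — a desk-scale backbone (3 conv+pool blocks on the native
  66×66 crop size) used for tests and synthetic-data experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .nn import Adam, Conv2D, Dense, Flatten, MaxPool2D, ReLU, Sequential, softmax, softmax_cross_entropy
from .phase_optics import Condition
from .segmentation import CellCrop

#: Fixed class ordering used everywhere: model outputs, reports, checkpoints.
CLASS_ORDER: tuple[str, str, str] = ("alive", "apoptosis", "necroptosis")

_VGG19_CFG = [64, 64, "P", 128, 128, "P", 256, 256, 256, 256, "P", 512, 512, 512, 512, "P", 512, 512, 512, 512, "P"]


@dataclass
class LabeledDataset:
    """A list of crops whose experiment condition serves as the class label."""

    crops: list[CellCrop]

    def __post_init__(self) -> None:
        for crop in self.crops:
            if crop.condition.value not in CLASS_ORDER:
                raise ValueError(f"label {crop.condition} not in {CLASS_ORDER}")

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_ORDER}
        for crop in self.crops:
            counts[crop.condition.value] += 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.array([crop.condition.value for crop in self.crops])

    def __len__(self) -> int:
        return len(self.crops)

    def by_class(self) -> dict[str, list[CellCrop]]:
        groups: dict[str, list[CellCrop]] = {c: [] for c in CLASS_ORDER}
        for crop in self.crops:
            groups[crop.condition.value].append(crop)
        return groups


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters. All values are package defaults — none are
    dictated by the underlying method — and live here so runs are reproducible
    from the serialized config alone."""

    seed: int = 0
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    freeze_backbone: bool = True
    val_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class ClassifierModel:
    """Backbone + surgically attached head emitting 3-class probabilities."""

    backbone_name: str
    network: Sequential
    input_shape: tuple[int, int, int]
    head_start: int  # index of the first head layer (the FC-64) in network.layers
    last_pool_index: int  # index of the final pooling layer of the conv stack
    seed: int
    class_order: tuple[str, str, str] = CLASS_ORDER

    def backbone_forward(self, x: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Run the frozen part of the network (everything before the head)."""
        outs = []
        for i in range(0, len(x), chunk):
            h = x[i : i + chunk]
            for layer in self.network.layers[: self.head_start]:
                h = layer.forward(h)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def head_forward(self, feats: np.ndarray) -> np.ndarray:
        h = feats
        for layer in self.network.layers[self.head_start :]:
            h = layer.forward(h)
        return h

    def conv_feature_map(self, x: np.ndarray) -> np.ndarray:
        """Output of the convolutional stack (through the final pool).

        For ``vgg19_full`` on a (N, 224, 224, 3) batch this is (N, 7, 7, 512).
        """
        h = x
        for layer in self.network.layers[: self.last_pool_index + 1]:
            h = layer.forward(h)
        return h

    @property
    def head_layers(self) -> list:
        return self.network.layers[self.head_start :]


def balance_classes(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Subsample every class, without replacement, to the smallest class count.

    Crops are sorted by crop_id before the seeded draw so the result depends
    only on the dataset's contents, not its ordering. An already-balanced
    dataset is returned unchanged (the operation is idempotent).
    """
    counts = dataset.class_counts
    for cls, n in counts.items():
        if n == 0:
            raise ValueError(f"class {cls!r} has no crops")
    n_min = min(counts.values())
    if all(n == n_min for n in counts.values()):
        return dataset
    rng = np.random.default_rng(seed)
    kept: list[CellCrop] = []
    for cls in CLASS_ORDER:
        group = sorted(dataset.by_class()[cls], key=lambda c: c.crop_id)
        idx = rng.choice(len(group), size=n_min, replace=False)
        kept.extend(group[i] for i in sorted(idx))
    return LabeledDataset(crops=kept)


def split_train_val(
    dataset: LabeledDataset, val_fraction: float = 0.20, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified split: per class, floor(n·val_fraction) crops go to validation.

    The split is disjoint and exhaustive, reproducible under the seed, and
    invariant to the input ordering (crops are sorted by id before the
    seeded shuffle).
    """
    if not (0 < val_fraction < 1):
        raise ValueError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[CellCrop] = []
    val: list[CellCrop] = []
    for cls in CLASS_ORDER:
        group = sorted(dataset.by_class()[cls], key=lambda c: c.crop_id)
        if not group:
            continue
        n_val = int(np.floor(len(group) * val_fraction))
        if n_val == 0 or n_val == len(group):
            raise ValueError(
                f"class {cls!r} with {len(group)} crops cannot be split at fraction {val_fraction}"
            )
        perm = rng.permutation(len(group))
        val.extend(group[i] for i in perm[:n_val])
        train.extend(group[i] for i in perm[n_val:])
    return LabeledDataset(crops=train), LabeledDataset(crops=val)


def preprocess_crop(crop: CellCrop | np.ndarray, target_shape: tuple[int, int] = (66, 66)) -> np.ndarray:
    """Turn a phase crop into a network input tensor.

    The patch is min-max normalized to [0, 1] over the crop (a constant
    patch maps to all zeros), bilinearly resized to ``target_shape``, and
    replicated over three channels. Returns (H, W, 3) float32.
    """
    patch = crop.pixels if isinstance(crop, CellCrop) else np.asarray(crop)
    patch = patch.astype(np.float64)
    ptp = np.ptp(patch)
    if ptp == 0:
        norm = np.zeros_like(patch)
    else:
        norm = (patch - patch.min()) / ptp
    if norm.shape != tuple(target_shape):
        norm = resize(norm, target_shape, order=1, preserve_range=True, anti_aliasing=False)
    return np.repeat(norm[:, :, None], 3, axis=2).astype(np.float32)


def build_model(backbone: str = "small_cnn", seed: int = 0) -> ClassifierModel:
    """Assemble backbone + FC-64 / ReLU / FC-3 head with seeded initialization.

    The softmax is applied by :func:`predict` (and fused into the training
    loss), so the network's last layer is the 3-wide fully connected one.
    """
    rng = np.random.default_rng(seed)
    if backbone == "small_cnn":
        input_shape = (66, 66, 3)
        layers = [
            Conv2D(3, 8, 3, rng), ReLU(), MaxPool2D(),    # 66 -> 33
            Conv2D(8, 16, 3, rng), ReLU(), MaxPool2D(),   # 33 -> 16
            Conv2D(16, 32, 3, rng), ReLU(), MaxPool2D(),  # 16 -> 8
            Flatten(),
        ]
        last_pool_index = len(layers) - 2
        feat_dim = 8 * 8 * 32
    elif backbone == "vgg19_full":
        input_shape = (224, 224, 3)
        layers = []
        in_ch = 3
        for item in _VGG19_CFG:
            if item == "P":
                layers.append(MaxPool2D())
            else:
                layers.append(Conv2D(in_ch, int(item), 3, rng))
                layers.append(ReLU())
                in_ch = int(item)
        last_pool_index = len(layers) - 1
        layers += [
            Flatten(),
            Dense(7 * 7 * 512, 4096, rng), ReLU(),
            Dense(4096, 4096, rng), ReLU(),
        ]
        feat_dim = 4096
    else:
        raise ValueError(f"unknown backbone {backbone!r}")
    head_start = len(layers)
    layers += [Dense(feat_dim, 64, rng), ReLU(), Dense(64, 3, rng)]
    return ClassifierModel(
        backbone_name=backbone,
        network=Sequential(layers),
        input_shape=input_shape,
        head_start=head_start,
        last_pool_index=last_pool_index,
        seed=seed,
    )


def _as_arrays(model: ClassifierModel, dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray]:
    target = model.input_shape[:2]
    x = np.stack([preprocess_crop(c, target) for c in dataset.crops])
    class_index = {c: i for i, c in enumerate(model.class_order)}
    y = np.array([class_index[c.condition.value] for c in dataset.crops], dtype=np.int64)
    return x, y


def train_classifier(
    model: ClassifierModel,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    config: TrainConfig,
) -> tuple[ClassifierModel, list[dict]]:
    """Train the network with Adam on softmax cross-entropy.

    With ``freeze_backbone`` (the default) the conv stack keeps its seeded
    initialization as a fixed random-projection feature extractor and only
    the head is fitted — features are then computed once per crop, which
    keeps desk-scale training cheap. The best-validation-accuracy weights
    are restored before returning. History is a list of per-epoch dicts
    (epoch, train_loss, train_acc, val_loss, val_acc).
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if len(set(train_set.labels)) < 2:
        raise ValueError("training set must contain at least two classes")
    x_train, y_train = _as_arrays(model, train_set)
    x_val, y_val = _as_arrays(model, val_set)
    rng = np.random.default_rng(config.seed)

    if config.freeze_backbone:
        f_train = model.backbone_forward(x_train)
        f_val = model.backbone_forward(x_val)
        trainable = model.head_layers
        fwd_train = lambda idx: _forward_layers(trainable, f_train[idx])
        eval_train = lambda: _forward_layers(trainable, f_train)
        eval_val = lambda: _forward_layers(trainable, f_val)
    else:
        trainable = model.network.layers
        fwd_train = lambda idx: _forward_layers(trainable, x_train[idx])
        eval_train = lambda: _batched_forward(trainable, x_train)
        eval_val = lambda: _batched_forward(trainable, x_val)

    params = [p for layer in trainable for p in layer.params]
    opt = Adam(params, lr=config.learning_rate)

    history: list[dict] = []
    best_val_acc = -1.0
    best_weights = model.network.get_weights()
    n = len(x_train)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = fwd_train(idx)
            loss, grad = softmax_cross_entropy(logits, y_train[idx])
            for layer in reversed(trainable):
                grad = layer.backward(grad)
            opt.step([g for layer in trainable for g in layer.grads])
            losses.append(loss)
        train_logits = eval_train()
        val_logits = eval_val()
        train_loss, _ = softmax_cross_entropy(train_logits, y_train)
        val_loss, _ = softmax_cross_entropy(val_logits, y_val)
        train_acc = float(np.mean(train_logits.argmax(axis=1) == y_train))
        val_acc = float(np.mean(val_logits.argmax(axis=1) == y_val))
        history.append(
            {
                "epoch": epoch,
                "batch_loss": float(np.mean(losses)),
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_val_acc:
            best_val_acc = val_acc
            best_weights = model.network.get_weights()
    model.network.set_weights(best_weights)
    return model, history


def _forward_layers(layers: list, x: np.ndarray) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x)
    return x


def _batched_forward(layers: list, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    return np.concatenate([_forward_layers(layers, x[i : i + chunk]) for i in range(0, len(x), chunk)])


def predict(model: ClassifierModel, crops: list[CellCrop]) -> tuple[np.ndarray, np.ndarray]:
    """Per-crop class probabilities and argmax labels.

    Returns ``(probs, labels)`` with ``probs`` of shape (n, 3) in
    ``model.class_order`` (rows sum to 1) and ``labels`` an array of class
    names. Ties resolve to the earliest class in ``class_order``.
    """
    if not crops:
        raise ValueError("no crops to predict")
    target = model.input_shape[:2]
    for crop in crops:
        patch = crop.pixels if isinstance(crop, CellCrop) else crop
        if patch.ndim != 2:
            raise ValueError(f"crop must be a 2-D patch, got shape {patch.shape}")
    x = np.stack([preprocess_crop(c, target) for c in crops])
    feats = model.backbone_forward(x)
    logits = model.head_forward(feats)
    probs = softmax(logits.astype(np.float64))
    labels = np.array([model.class_order[i] for i in probs.argmax(axis=1)])
    return probs, labels


# ---------------------------------------------------------------------------
# Checkpoints: npz weights + JSON descriptor


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = model.network.get_weights()
    np.savez(path.with_suffix(".npz"), *weights)
    descriptor = {
        "format_version": 1,
        "backbone": model.backbone_name,
        "input_shape": list(model.input_shape),
        "class_order": list(model.class_order),
        "head": ["dense-64", "relu", "dense-3", "softmax"],
        "seed": model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(descriptor, indent=1, sort_keys=True))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    descriptor = json.loads(path.with_suffix(".json").read_text())
    model = build_model(descriptor["backbone"], seed=descriptor["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        weights = [data[k] for k in data.files]
    model.network.set_weights(weights)
    return model
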
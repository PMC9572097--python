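"""Model assembly and the desk-scale training/evaluation harness.

The pipeline mirrors the published architecture at toy scale: a pluggable
convolutional backbone produces a feature map, the soft-attention module
refines and pools it, the flattened image features are (optionally) fused
with the metadata head's output, and a dense softmax layer classifies.

Optimization follows the published schedule: Adam (lr 0.001, epsilon 0.1),
learning rate reduced by a factor 0.2 on a validation-accuracy plateau down
to a floor of 1e-7, early stopping when validation accuracy has not improved
for 25 epochs (best weights restored), batch size 32, and optional
augmentation by rotation (±180°), width/height shift (±0.1), zoom (±0.1) and
horizontal/vertical flips with reflect fill.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import losses
from .metadata_fusion import MetadataHead
from .metrics import MetricsReport, confusion_matrix, metric_report
from .nn import Adam, Conv2D, Dense, Flatten, Layer, MaxPool2D, Param, ReLU, Sequential, softmax
from .soft_attention import SoftAttentionModule

__all__ = [
    "TrainConfig",
    "TinyBackbone",
    "LesionClassifier",
    "build_model",
    "augment",
    "augment_batch",
    "ReduceLROnPlateau",
    "EarlyStopping",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the published schedule."""

    learning_rate: float = 1e-3
    lr_reduce_factor: float = 0.2
    lr_patience: int = 10          # epochs without val-accuracy gain before reducing
    lr_min: float = 1e-7
    optimizer_epsilon: float = 0.1
    max_epochs: int = 250
    early_stop_patience: int = 25  # on validation accuracy
    batch_size: int = 32
    seed: int = 0
    # augmentation
    augment: bool = True
    rotation_range: float = 180.0  # degrees
    shift_range: float = 0.1       # fraction of each spatial dim
    zoom_range: float = 0.1
    horizontal_flip: bool = True
    vertical_flip: bool = True
    # model
    use_metadata: bool = False
    weight_scheme: str = "none"    # none | original | balanced
    restore_best_weights: bool = True  # roll back to the best-val-accuracy epoch
    n_attention_maps: int = 16
    attention_ksize: int = 3
    sa_dropout: float = 0.5
    meta_units: int = 4096
    backbone_channels: tuple[int, ...] = (8, 16)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.lr_min <= 0 or self.lr_reduce_factor <= 0:
            raise ValueError("all rates must be positive")
        if self.early_stop_patience < 1 or self.lr_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.weight_scheme not in ("none", "original", "balanced"):
            raise ValueError(f"unknown weight_scheme {self.weight_scheme!r}")


class TinyBackbone(Sequential):
    """Small conv/pool feature extractor standing in for the published
    backbones; attaches through the same feature-map contract (image in,
    h'×w'×d map out, ``out_channels`` = d)."""

    def __init__(self, channels: tuple[int, ...] = (8, 16), in_ch: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng(0)
        layers: list[Layer] = []
        prev = in_ch
        for i, c in enumerate(channels):
            layers += [Conv2D(prev, c, 3, rng=rng, name=f"bb{i}"), ReLU(), MaxPool2D(2)]
            prev = c
        super().__init__(*layers)
        self.out_channels = prev


class LesionClassifier:
    """backbone → soft-attention module → flatten → (⊕ metadata head) →
    dense → softmax."""

    def __init__(self, backbone, n_classes: int, input_shape: tuple[int, int],
                 meta_dim: int | None = None, config: TrainConfig | None = None,
                 rng: np.random.Generator | None = None) -> None:
        config = config or TrainConfig()
        rng = rng or np.random.default_rng(config.seed)
        self.backbone = backbone
        self.n_classes = n_classes
        self.sa_module = SoftAttentionModule(
            backbone.out_channels, n_maps=config.n_attention_maps,
            ksize=config.attention_ksize, dropout_p=config.sa_dropout, rng=rng)
        self.flatten = Flatten()

        # dry run to size the classifier head
        h, w = input_shape
        probe = np.zeros((1, h, w, 3))
        feat = self.flatten.forward(self.sa_module.forward(self.backbone.forward(probe)))
        self.image_feature_dim = feat.shape[1]

        self.meta_head: MetadataHead | None = None
        in_dim = self.image_feature_dim
        if meta_dim is not None:
            self.meta_head = MetadataHead(meta_dim, units=config.meta_units, rng=rng)
            in_dim += config.meta_units
        self.classifier = Dense(in_dim, n_classes, rng=rng, name="head")
        self._cache: tuple | None = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = [*self.backbone.params(), *self.sa_module.params()]
        if self.meta_head is not None:
            out.extend(self.meta_head.params())
        out.extend(self.classifier.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]

    # -- forward / backward -------------------------------------------------
    def forward(self, x_img: np.ndarray, x_meta: np.ndarray | None = None,
                training: bool = False) -> np.ndarray:
        """Class-probability matrix (N, C); rows sum to 1."""
        if self.meta_head is not None and x_meta is None:
            raise ValueError("model was built with a metadata branch; x_meta is required")
        feat = self.flatten.forward(
            self.sa_module.forward(self.backbone.forward(x_img, training=training),
                                   training=training))
        if self.meta_head is not None:
            meta_feat = self.meta_head.forward(np.asarray(x_meta, dtype=np.float64))
            fused = np.concatenate([feat, meta_feat], axis=1)
        else:
            fused = feat
        logits = self.classifier.forward(fused)
        probs = softmax(logits, axis=1)
        self._cache = (probs,)
        return probs

    def backward_from_logit_grad(self, dlogits: np.ndarray) -> None:
        dfused = self.classifier.backward(dlogits)
        dfeat = dfused[:, :self.image_feature_dim]
        if self.meta_head is not None:
            self.meta_head.backward(dfused[:, self.image_feature_dim:])
        self.backbone.backward(self.sa_module.backward(self.flatten.backward(dfeat)))


def build_model(config: TrainConfig, backbone=None, n_classes: int = 7,
                input_shape: tuple[int, int] = (64, 64),
                meta_dim: int | None = None) -> LesionClassifier:
    """Assemble the full classifier; same config+seed gives identical
    initial parameters."""
    rng = np.random.default_rng(config.seed)
    if backbone is None:
        backbone = TinyBackbone(config.backbone_channels, rng=rng)
    if config.use_metadata and meta_dim is None:
        raise ValueError("use_metadata=True requires meta_dim")
    if not config.use_metadata:
        meta_dim = None
    return LesionClassifier(backbone, n_classes, input_shape, meta_dim=meta_dim,
                            config=config, rng=rng)


# -- augmentation ------------------------------------------------------------

def augment(image: np.ndarray, rng: np.random.Generator, config: TrainConfig) -> np.ndarray:
    """Random rotation/shift/zoom/flip of one (h, w, c) image, reflect fill.

    With all transform ranges zero and flips disabled this is the identity.
    The label is untouched by construction.
    """
    x = np.asarray(image, dtype=np.float64)
    h, w = x.shape[:2]
    angle = np.deg2rad(rng.uniform(-config.rotation_range, config.rotation_range)) \
        if config.rotation_range else 0.0
    zoom = 1.0 + (rng.uniform(-config.zoom_range, config.zoom_range) if config.zoom_range else 0.0)
    dy = rng.uniform(-config.shift_range, config.shift_range) * h if config.shift_range else 0.0
    dx = rng.uniform(-config.shift_range, config.shift_range) * w if config.shift_range else 0.0
    flip_h = config.horizontal_flip and rng.random() < 0.5
    flip_v = config.vertical_flip and rng.random() < 0.5

    if angle or zoom != 1.0 or dy or dx:
        c, s = np.cos(angle), np.sin(angle)
        inv = np.array([[c, s], [-s, c]]) / zoom  # output->input rotation/zoom
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - inv @ (center + np.array([dy, dx]))
        out = np.empty_like(x)
        for ch in range(x.shape[2]):
            out[..., ch] = ndimage.affine_transform(
                x[..., ch], inv, offset=offset, order=1, mode="reflect")
        x = out
    if flip_h:
        x = x[:, ::-1]
    if flip_v:
        x = x[::-1, :]
    return np.ascontiguousarray(x)


def augment_batch(images: np.ndarray, rng: np.random.Generator,
                  config: TrainConfig) -> np.ndarray:
    return np.stack([augment(im, rng, config) for im in images])


# -- schedules ---------------------------------------------------------------

class ReduceLROnPlateau:
    """Multiply the learning rate by ``factor`` when the monitored metric has
    not improved for ``patience`` consecutive epochs, never below ``min_lr``."""

    def __init__(self, optimizer: Adam | None = None, factor: float = 0.2,
                 patience: int = 10, min_lr: float = 1e-7,
                 initial_lr: float | None = None) -> None:
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.lr = initial_lr if initial_lr is not None else (optimizer.lr if optimizer else 1e-3)
        self.best = -np.inf
        self.wait = 0

    def step(self, metric: float) -> float:
        """Report this epoch's metric; returns the learning rate to use next."""
        if metric > self.best:
            self.best = metric
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.wait = 0
        if self.optimizer is not None:
            self.optimizer.lr = self.lr
        return self.lr


class EarlyStopping:
    """Stop when the monitored metric has not improved for ``patience``
    epochs; remembers the best epoch so its weights can be restored."""

    def __init__(self, patience: int = 25) -> None:
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = 0
        self.wait = 0

    def step(self, metric: float, epoch: int) -> bool:
        if metric > self.best:
            self.best = metric
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


# -- training / evaluation ---------------------------------------------------

def _class_weights(scheme: str, labels: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_classes)
    if scheme == "none":
        return np.ones(n_classes)
    if np.any(counts == 0):
        raise ValueError(
            f"weight scheme {scheme!r} needs every class present in the training "
            f"split; counts {counts.tolist()}")
    if scheme == "original":
        return losses.class_weights_original(counts)
    return losses.class_weights_balanced(counts)


def _accuracy(model: LesionClassifier, x, meta, y, batch: int) -> tuple[float, np.ndarray]:
    probs = predict_probs(model, x, meta, batch)
    return float(np.mean(probs.argmax(axis=1) == y)), probs


def predict_probs(model: LesionClassifier, x: np.ndarray, meta: np.ndarray | None,
                  batch: int = 64) -> np.ndarray:
    out = np.empty((len(x), model.n_classes))
    for i in range(0, len(x), batch):
        mb = meta[i:i + batch] if meta is not None else None
        out[i:i + batch] = model.forward(x[i:i + batch], mb, training=False)
    return out


def train(model: LesionClassifier, train_set, val_set, config: TrainConfig,
          verbose: bool = False) -> dict:
    """Train with weighted cross-entropy under the published schedule.

    ``train_set``/``val_set`` are ``(images, meta_or_None, labels)`` triples
    with images already preprocessed to floats.  Returns a history dict with
    per-epoch train/val loss and accuracy, the learning-rate trace, the best
    epoch, and the model restored to its best-validation-accuracy weights.
    """
    x_tr, m_tr, y_tr = train_set
    x_va, m_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    y_tr = np.asarray(y_tr, dtype=np.int64)
    y_va = np.asarray(y_va, dtype=np.int64)
    weights = _class_weights(config.weight_scheme, y_tr, model.n_classes)

    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.params(), lr=config.learning_rate, epsilon=config.optimizer_epsilon)
    scheduler = ReduceLROnPlateau(opt, factor=config.lr_reduce_factor,
                                  patience=config.lr_patience, min_lr=config.lr_min)
    stopper = EarlyStopping(config.early_stop_patience)
    best_state = model.get_state()
    history: dict = {"train_loss": [], "train_acc": [], "val_loss": [],
                     "val_acc": [], "lr": [], "weights": weights.tolist()}

    n = len(x_tr)
    eye = np.eye(model.n_classes)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = x_tr[idx]
            if config.augment:
                xb = augment_batch(xb, rng, config)
            mb = m_tr[idx] if m_tr is not None else None
            yb = y_tr[idx]
            probs = model.forward(xb, mb, training=True)
            onehot = eye[yb]
            loss = losses.weighted_cce(onehot, probs, weights)
            # softmax+weighted-CCE gradient w.r.t. logits
            dlogits = (probs - onehot) * weights[yb][:, None] / len(yb)
            opt.zero_grad()
            model.backward_from_logit_grad(dlogits)
            opt.step()
            ep_loss += loss * len(yb)
            ep_correct += int(np.sum(probs.argmax(axis=1) == yb))

        val_acc, val_probs = _accuracy(model, x_va, m_va, y_va, config.batch_size)
        val_loss = losses.weighted_cce(eye[y_va], val_probs, weights)
        history["train_loss"].append(ep_loss / n)
        history["train_acc"].append(ep_correct / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch:3d}  loss {ep_loss / n:.4f}  acc {ep_correct / n:.3f}  "
                  f"val_acc {val_acc:.3f}  lr {opt.lr:.2e}")

        if val_acc > stopper.best:
            best_state = model.get_state()
        stop = stopper.step(val_acc, epoch)
        scheduler.step(val_acc)
        if stop:
            break

    if config.restore_best_weights:
        model.set_state(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["best_val_acc"] = stopper.best
    history["epochs_run"] = len(history["val_acc"])
    return history


def evaluate(model: LesionClassifier, test_set, batch: int = 64) -> MetricsReport:
    """Deterministic evaluation (dropout off, argmax ties to the lowest
    class index) returning the full metric report including AUC."""
    x, meta, y = test_set
    if len(x) == 0:
        raise ValueError("test set is empty")
    y = np.asarray(y, dtype=np.int64)
    probs = predict_probs(model, x, meta, batch)
    pred = probs.argmax(axis=1)  # np.argmax returns the first (lowest) max index
    mat = confusion_matrix(y, pred, model.n_classes)
    return metric_report(mat, scores=probs, true_labels=y)


def save_checkpoint(model: LesionClassifier, path) -> None:
    """Persist model weights as an ``.npz`` archive."""
    np.savez(Path(path), **model.get_state())


def load_checkpoint(model: LesionClassifier, path) -> None:
    with np.load(Path(path)) as data:
        model.set_state({k: data[k] for k in data.files})
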
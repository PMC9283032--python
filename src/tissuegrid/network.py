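"""Classifier assembly and training.

The network follows the two-branch idea of bilinear pooling plus soft
attention: convolutional features (with no global average pooling — the
spatial map is flattened instead) feed a bank of bilinear nodes producing an
m-dimensional "bilinear vector"; a soft-attention gate reweights its
elements; a dense softmax head classifies.  Training uses Adam (lr 3e-4,
beta1 0.9, weight decay 1e-4 by default, batch 32) with the learning rate
multiplied by 0.1 whenever the epoch-mean training loss has not reached a
new minimum for a patience window — the "drop to one-tenth on plateau"
schedule.  Augmentation is 90-degree rotations, horizontal flips, and
optional per-channel colour standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "AugmentFlags",
    "ModelConfig",
    "TrainConfig",
    "PatchDataset",
    "TissueClassifier",
    "build_classifier",
    "train_classifier",
    "augment_patch",
    "predict_patch",
    "fine_tune",
    "stratified_split",
    "save_checkpoint",
    "load_checkpoint",
    "evaluate_accuracy",
]

_TINY_CHANNELS = (16, 32, 32)  # three conv blocks, total stride 8


class ConfigError(ValueError):
    pass


@dataclass
class AugmentFlags:
    rotate90s: bool = True
    hflip: bool = True
    color_normalize: bool = False


@dataclass
class ModelConfig:
    n_classes: int
    backbone: str = "tiny_cnn"
    input_size: int = 32
    reduce_channels: int | None = None
    bilinear_m: int = 32
    bilinear_k: int = 8
    use_bilinear: bool = True
    use_attention: bool = True
    shared_f: bool = False
    pretrained_source: str = "none"

    def __post_init__(self) -> None:
        if self.backbone != "tiny_cnn":
            raise ConfigError(
                f"backbone {self.backbone!r} is not available; this package "
                "ships the CPU-scale 'tiny_cnn' backbone"
            )
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.input_size % 8 != 0 or self.input_size < 16:
            raise ConfigError(
                f"input_size {self.input_size} must be a multiple of the "
                "backbone's total stride (8) and at least 16"
            )


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 80
    lr: float = 3e-4
    weight_decay: float = 1e-4
    beta1: float = 0.9
    plateau_patience: int = 30
    plateau_factor: float = 0.1
    plateau_tol: float = 1e-4
    seed: int = 0
    augment: AugmentFlags = field(default_factory=AugmentFlags)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ConfigError("lr must be positive")
        if not (0 < self.plateau_factor < 1):
            raise ConfigError("plateau_factor must be in (0, 1)")
        if isinstance(self.augment, dict):
            self.augment = AugmentFlags(**self.augment)


@dataclass
class PatchDataset:
    """Labelled RGB patches with a class vocabulary."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int
    class_names: list[str]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[3] != 3:
            raise ValueError(f"images must be (N, H, W, 3), got {self.images.shape}")
        if self.images.shape[1] != self.images.shape[2]:
            raise ValueError("patches must be square")
        if len(self.labels) != len(self.images):
            raise ValueError("labels and images lengths differ")
        n = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= n):
            raise ValueError(f"labels must lie in [0, {n})")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def patch_size(self) -> int:
        return self.images.shape[1]

    def subset(self, idx) -> "PatchDataset":
        return PatchDataset(self.images[idx], self.labels[idx], self.class_names)


class TissueClassifier:
    """A built network plus its config, class vocabulary, and preprocessing."""

    def __init__(self, net: nn.Sequential, config: ModelConfig,
                 class_names: list[str] | None = None,
                 color_normalize: bool = False):
        self.net = net
        self.config = config
        self.class_names = class_names or [f"C{i}" for i in range(config.n_classes)]
        self.color_normalize = color_normalize
        self.history: dict | None = None

    @property
    def dtype(self):
        for _, p, _ in self.net.parameters():
            return p.dtype
        return np.float32

    # -- preprocessing -----------------------------------------------------
    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """uint8/float (B, H, W, 3) -> NCHW in the net's dtype, scaled or
        standardized."""
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if images.dtype == np.uint8:
            x = x / 255.0
        if self.color_normalize:
            mean = x.mean(axis=(1, 2), keepdims=True)
            std = x.std(axis=(1, 2), keepdims=True)
            x = (x - mean) / (std + 1e-8)
        return x.transpose(0, 3, 1, 2)

    # -- inference ---------------------------------------------------------
    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        return self.net.forward(self.preprocess(images), train=False)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return nn.softmax(self.predict_logits(images))

    def last_conv_layer(self) -> str:
        """Name of the last convolutional layer of the backbone (the
        default Grad-CAM hook)."""
        last = None
        for name, layer in self.net.layers:
            if name == "flatten":
                break
            if isinstance(layer, nn.Conv2d):
                last = name
        return last


def _build_net(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[tuple[str, nn.Layer]] = []
    in_ch = 3
    for i, out_ch in enumerate(_TINY_CHANNELS, start=1):
        layers.append((f"conv{i}", nn.Conv2d(in_ch, out_ch, 3, rng)))
        layers.append((f"relu{i}", nn.ReLU()))
        layers.append((f"pool{i}", nn.MaxPool2d()))
        in_ch = out_ch
    spatial = cfg.input_size // 8
    if cfg.reduce_channels is not None:
        layers.append(("reduce", nn.Conv2d(in_ch, cfg.reduce_channels, 1, rng)))
        in_ch = cfg.reduce_channels
    layers.append(("flatten", nn.Flatten()))
    n_feat = in_ch * spatial * spatial
    head_in = n_feat
    if cfg.use_bilinear:
        layers.append(("bilinear", nn.BilinearLayerNN(
            n_feat, cfg.bilinear_m, cfg.bilinear_k, rng, shared_f=cfg.shared_f)))
        head_in = cfg.bilinear_m
    if cfg.use_attention:
        layers.append(("attention", nn.AttentionGateNN(head_in, rng)))
    layers.append(("head", nn.Dense(head_in, cfg.n_classes, rng)))
    return nn.Sequential(layers)


def build_classifier(cfg: ModelConfig, seed: int,
                     class_names: list[str] | None = None) -> TissueClassifier:
    """Deterministically construct the classifier for a config and seed."""
    rng = np.random.default_rng(seed)
    return TissueClassifier(_build_net(cfg, rng), cfg, class_names)


def augment_patch(img: np.ndarray, flags: AugmentFlags,
                  rng: np.random.Generator) -> np.ndarray:
    """Label-preserving augmentation of one 8-bit RGB patch.

    Rotations by uniformly drawn multiples of 90 degrees, horizontal flip
    with probability 1/2, and per-channel standardization (mean 0, std 1
    over the patch) when ``color_normalize`` is set; identity when all
    flags are off.  The output is uint8 unless standardized (then float64).
    """
    out = img
    if flags.rotate90s:
        out = np.rot90(out, k=int(rng.integers(0, 4)), axes=(0, 1))
    if flags.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if flags.color_normalize:
        out = np.asarray(out, dtype=np.float64)
        mean = out.mean(axis=(0, 1))
        std = out.std(axis=(0, 1))
        out = (out - mean) / (std + 1e-8)
    return np.ascontiguousarray(out) if out is not img else img


def _eval_loss_acc(model: TissueClassifier, ds: PatchDataset,
                   batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(ds), batch_size):
        imgs, labels = ds.images[i : i + batch_size], ds.labels[i : i + batch_size]
        logits = model.predict_logits(imgs)
        loss, _ = nn.cross_entropy_with_logits(logits, labels)
        losses.append(loss * len(labels))
        correct += int((logits.argmax(axis=1) == labels).sum())
    return float(np.sum(losses) / len(ds)), correct / len(ds)


def train_classifier(model: TissueClassifier, train: PatchDataset,
                     val: PatchDataset, cfg: TrainConfig):
    """Cross-entropy training with Adam and the plateau LR schedule.

    Returns (model, history); history holds per-epoch lists ``train_loss``,
    ``val_loss``, ``val_acc``, and ``lr`` (the rate used during that epoch).
    Fully reproducible given cfg.seed.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val datasets must be non-empty")
    if train.patch_size != model.config.input_size:
        raise ValueError(
            f"patches are {train.patch_size}px but the model expects "
            f"{model.config.input_size}px"
        )
    model.color_normalize = cfg.augment.color_normalize
    opt = nn.Adam(model.net, lr=cfg.lr, beta1=cfg.beta1,
                  weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
    best = np.inf
    stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        batch_losses = []
        for start in range(0, len(train), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs = [augment_patch(train.images[i], cfg.augment, rng)
                    for i in idx]
            if cfg.augment.color_normalize:
                x = np.stack(imgs).transpose(0, 3, 1, 2).astype(model.dtype)
            else:
                x = model.preprocess(np.stack(imgs))
            labels = train.labels[idx]
            logits = model.net.forward(x, train=True)
            loss, gout = nn.cross_entropy_with_logits(logits, labels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {start // cfg.batch_size} (lr={opt.lr:g})"
                )
            model.net.zero_grad()
            model.net.backward(gout)
            opt.step()
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        val_loss, val_acc = _eval_loss_acc(model, val, cfg.batch_size)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(opt.lr)
        # plateau rule: no new minimum for plateau_patience epochs -> drop LR
        if train_loss < best - cfg.plateau_tol:
            best = train_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                stale = 0
    model.history = history
    return model, history


def predict_patch(model: TissueClassifier, img: np.ndarray) -> np.ndarray:
    """Class-probability vector for one patch (no silent resizing)."""
    img = np.asarray(img)
    s = model.config.input_size
    if img.shape[:2] != (s, s):
        raise ValueError(f"patch is {img.shape[:2]}, model expects ({s}, {s})")
    return model.predict_proba(img[None])[0]


def stratified_split(ds: PatchDataset, val_frac: float = 0.2,
                     seed: int = 0) -> tuple[PatchDataset, PatchDataset]:
    """Per-class shuffled split keeping class proportions."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for c in np.unique(ds.labels):
        idx = np.where(ds.labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_frac * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(val_idx))


def evaluate_accuracy(model: TissueClassifier, ds: PatchDataset,
                      batch_size: int = 64) -> float:
    _, acc = _eval_loss_acc(model, ds, batch_size)
    return acc


# ---------------------------------------------------------------------------
# Checkpoints and fine-tuning


def save_checkpoint(model: TissueClassifier, path) -> str:
    """Single-archive checkpoint: parameters + config + vocabulary +
    pretraining provenance + preprocessing flag.  Returns the written path
    (``.npz`` is appended when missing)."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    meta = {
        "config": asdict(model.config),
        "class_names": model.class_names,
        "color_normalize": model.color_normalize,
    }
    arrays = {f"param/{k}": v for k, v, _ in model.net.parameters()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_checkpoint(path) -> TissueClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    cfg = ModelConfig(**meta["config"])
    model = build_classifier(cfg, seed=0, class_names=meta["class_names"])
    model.color_normalize = meta["color_normalize"]
    model.net.load_state_dict(state)
    return model


def fine_tune(checkpoint, new_train: PatchDataset, cfg: TrainConfig,
              new_val: PatchDataset | None = None) -> TissueClassifier:
    """Transfer learning: load all weights except the classification head.

    The head is re-initialized for the new vocabulary when its size differs
    from the checkpoint's; when the vocabularies match in size the head is
    kept, so fine-tuning for zero epochs is the identity.  Any non-head
    shape mismatch is a checkpoint error.  Returns the trained model (its
    ``history`` attribute holds the training record).
    """
    src = checkpoint if isinstance(checkpoint, TissueClassifier) \
        else load_checkpoint(checkpoint)
    n_new = len(new_train.class_names)
    cfg_new = ModelConfig(**{**asdict(src.config),
                             "n_classes": n_new,
                             "pretrained_source": "checkpoint"})
    model = build_classifier(cfg_new, seed=cfg.seed,
                             class_names=new_train.class_names)
    model.color_normalize = src.color_normalize
    state = src.net.state_dict()
    keep_head = n_new == src.config.n_classes
    for name, layer in model.net.layers:
        if name == "head" and not keep_head:
            continue
        for key in layer.params:
            full = f"{name}.{key}"
            if state[full].shape != layer.params[key].shape:
                raise ValueError(
                    f"checkpoint incompatible: parameter {full} has shape "
                    f"{state[full].shape}, model expects {layer.params[key].shape}"
                )
            layer.params[key] = state[full].copy()
    if cfg.epochs == 0:
        model.history = {"train_loss": [], "val_loss": [], "val_acc": [], "lr": []}
        return model
    if new_val is None:
        tr, new_val = stratified_split(new_train, 0.2, cfg.seed)
    else:
        tr = new_train
    model, _ = train_classifier(model, tr, new_val, cfg)
    return model
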
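"""Training, checkpoint selection, inference, and checkpoint I/O.

Checkpoint selection follows the lowest-validation-loss rule: the selected
epoch minimizes validation loss, with ties broken toward higher validation
accuracy and then toward the earlier epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from octmargin.cnn import engine
from octmargin.cnn.model import ArchConfig, PatchCNN, build_model
from octmargin.patchgen import POSITIVE, Patch

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "predict_patches",
    "patches_to_arrays",
    "select_epoch",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    class_balance: str = "none"  # {"none", "weighted"}

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is implemented")
        if self.class_balance not in ("none", "weighted"):
            raise ValueError("class_balance must be 'none' or 'weighted'")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def selected_epoch(self) -> int:
        return select_epoch(self.val_loss, self.val_accuracy)


def select_epoch(val_loss: Sequence[float], val_accuracy: Sequence[float]) -> int:
    """Index of the checkpoint epoch: min val loss; ties → max val accuracy,
    then earliest epoch."""
    if not val_loss:
        raise ValueError("empty history")
    order = sorted(range(len(val_loss)), key=lambda i: (val_loss[i], -val_accuracy[i], i))
    return order[0]


def normalize_patch_array(x: np.ndarray) -> np.ndarray:
    """Per-patch standardization: zero mean, unit variance per image.

    Centering keeps the ReLU stack out of the all-dead regime that raw
    non-negative intensities push it into, and the per-patch variance scaling
    removes margin-to-margin brightness offsets so that features learned on
    one scan transfer to another. ``x`` is (N, H, W) or (N, H, W, 1) in
    [0, 1]; returns float32 of the same shape.
    """
    x = np.asarray(x, dtype=np.float32)
    axes = tuple(range(1, x.ndim))
    mean = x.mean(axis=axes, keepdims=True)
    std = x.std(axis=axes, keepdims=True)
    return (x - mean) / (std + 1e-6)


def patches_to_arrays(patches: Sequence[Patch]) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches into standardized (N, H, W, 1) float32 plus 0/1 labels.

    Integer inputs are scaled by their dtype maximum to [0, 1] first; float
    inputs are assumed pre-scaled. Each patch is then standardized to zero
    mean and unit variance (see :func:`normalize_patch_array`).
    """
    if len(patches) == 0:
        h, w = 0, 0
        return np.zeros((0, h, w, 1), np.float32), np.zeros(0, np.int64)
    x = np.stack([p.pixels for p in patches]).astype(np.float32)
    dt = patches[0].pixels.dtype
    if np.issubdtype(dt, np.integer):
        x /= np.iinfo(dt).max
    x = normalize_patch_array(x)
    y = np.array([1 if p.label == POSITIVE else 0 for p in patches], dtype=np.int64)
    return x[..., None], y


def _forward_loss(model: PatchCNN, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    """Mean loss and accuracy over a full split, batched."""
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = engine.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: PatchCNN,
    train_patches: Sequence[Patch] | tuple[np.ndarray, np.ndarray],
    val_patches: Sequence[Patch] | tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig = TrainConfig(),
) -> tuple[PatchCNN, TrainHistory]:
    """Train and return (checkpoint at the selected epoch, history).

    Deterministic under a fixed seed and thread configuration. Raises on
    single-class training data and aborts with diagnostics on NaN loss.
    """
    x_tr, y_tr = train_patches if isinstance(train_patches, tuple) else patches_to_arrays(train_patches)
    x_va, y_va = val_patches if isinstance(val_patches, tuple) else patches_to_arrays(val_patches)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation splits must be non-empty")
    classes, counts = np.unique(y_tr, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class; cannot fit a classifier")

    weights = None
    if cfg.class_balance == "weighted":
        w_by_class = len(y_tr) / (2.0 * counts.astype(np.float64))
        weights = w_by_class[np.searchsorted(classes, y_tr)]

    rng = np.random.default_rng(cfg.seed)
    opt = engine.Adam(model.params(), lr=cfg.learning_rate)
    history = TrainHistory()
    best_weights = None
    best_key: tuple[float, float, int] | None = None

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x_tr[idx], train=True)
            loss, dlogits = engine.softmax_cross_entropy(
                logits, y_tr[idx], None if weights is None else weights[idx]
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {i // cfg.batch_size}: "
                    f"loss={loss}; consider lowering the learning rate"
                )
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss * len(idx))
        history.train_loss.append(float(np.sum(epoch_losses) / len(x_tr)))

        val_loss, val_acc = _forward_loss(model, x_va, y_va, cfg.batch_size)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

        key = (val_loss, -val_acc, epoch)
        if best_key is None or key < best_key:
            best_key = key
            best_weights = model.get_weights()

    best_model = build_model(model.arch, seed=cfg.seed)
    best_model.set_weights(best_weights)
    assert history.selected_epoch == best_key[2]
    return best_model, history


def predict_patches(
    model: PatchCNN,
    patches: Sequence[Patch] | np.ndarray,
    batch_size: int = 64,
) -> np.ndarray:
    """Suspicious-class probability for each patch; independent of batching."""
    if isinstance(patches, np.ndarray):
        x = patches
    else:
        if len(patches) == 0:
            return np.zeros(0, dtype=np.float64)
        x, _ = patches_to_arrays(patches)
    if len(x) == 0:
        return np.zeros(0, dtype=np.float64)
    h, w, c = model.arch.input_shape
    if x.shape[1:] != (h, w, c):
        raise ValueError(f"patch shape {x.shape[1:]} does not match model input {(h, w, c)}")
    out = [model.predict_proba(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(out)


def save_model(model: PatchCNN, path: str | Path) -> None:
    """Serialize weights + architecture to a single .npz checkpoint."""
    arch = model.arch
    meta = json.dumps(
        {
            "conv_channels": list(arch.conv_channels),
            "fc_sizes": list(arch.fc_sizes),
            "input_shape": list(arch.input_shape),
            "pool_after": list(arch.pool_after),
            "dropout_rate": arch.dropout_rate,
            "kernel_size": arch.kernel_size,
        }
    )
    weights = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, arch=np.array(meta), **weights)


def load_model(path: str | Path) -> PatchCNN:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["arch"]))
    arch = ArchConfig(
        conv_channels=tuple(meta["conv_channels"]),
        fc_sizes=tuple(meta["fc_sizes"]),
        input_shape=tuple(meta["input_shape"]),
        pool_after=tuple(meta["pool_after"]),
        dropout_rate=meta["dropout_rate"],
        kernel_size=meta["kernel_size"],
    )
    model = build_model(arch, seed=0)
    n = len(model.get_weights())
    model.set_weights([data[f"w{i}"] for i in range(n)])
    return model
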
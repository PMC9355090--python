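"""Training and inference for the 3-class seedling networks.

Cross-entropy loss minimised with Adam over mini-batches of 32 by
default; every epoch records training and validation loss/accuracy, and
the parameters of the best-validation-accuracy epoch (ties broken by
lower validation loss) are kept as the final model. One config seed
drives weight init, shuffling and batch order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..evaluation import LABELS
from ..extraction import NET_INPUT_SIZE, extract_seedling, read_image, resize_for_net
from .layers import Module

__all__ = [
    "TrainingConfig",
    "TrainResult",
    "Adam",
    "softmax",
    "cross_entropy",
    "load_split_arrays",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

_LABEL_TO_INDEX = {name: i for i, name in enumerate(LABELS)}


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 20
    seed: int = 0
    freeze: bool = False  # skip optimiser updates (diagnostic)

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")


@dataclass
class TrainResult:
    model: Module
    history: dict[str, list[float]]
    step_losses: list[float]
    best_epoch: int
    best_val_accuracy: float


class Adam:
    """Adam optimiser over a Module's named parameters."""

    def __init__(self, module: Module, lr: float, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.module = module
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, module, key in self.module.named_parameters():
            grad = module.grads.get(key)
            if grad is None:
                continue
            if name not in self.m:
                self.m[name] = np.zeros_like(grad)
                self.v[name] = np.zeros_like(grad)
            self.m[name] = b1 * self.m[name] + (1 - b1) * grad
            self.v[name] = b2 * self.v[name] + (1 - b2) * grad * grad
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            module.params[key] = (
                module.params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(probs[np.arange(n), targets], 1e-12, None)).mean())
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, (grad / n).astype(np.float32)


def _prepare(image: np.ndarray) -> np.ndarray:
    """HWC uint8 → CHW float32 standardised to [-1, 1]."""
    x = np.asarray(image, dtype=np.float32) / 255.0
    return ((x - 0.5) / 0.5).transpose(2, 0, 1)


def load_split_arrays(
    manifest: pd.DataFrame,
    split: str,
    root: str | Path = ".",
    preprocess: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Load one split as (X, y): X is (N, 3, 224, 224) float32, y int labels.

    ``preprocess=True`` runs background removal before the bilinear resize,
    matching the extracted-seedling training regime.
    """
    rows = manifest[manifest["split"] == split] if "split" in manifest.columns else manifest
    images, targets = [], []
    root = Path(root)
    for _, row in rows.iterrows():
        img = read_image(str(root / row["path"]))
        if preprocess:
            img = extract_seedling(img)
        img = resize_for_net(img)
        images.append(_prepare(img))
        targets.append(_LABEL_TO_INDEX[row["label"]])
    if not images:
        return np.zeros((0, 3, NET_INPUT_SIZE, NET_INPUT_SIZE), np.float32), np.zeros(0, np.int64)
    return np.stack(images), np.asarray(targets, dtype=np.int64)


def _evaluate(model: Module, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    model.eval()
    losses, correct = [], 0
    for lo in range(0, len(x), batch_size):
        xb, yb = x[lo : lo + batch_size], y[lo : lo + batch_size]
        logits = model(xb)
        loss, _ = cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    model.train()
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: Module,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    config: TrainingConfig = TrainingConfig(),
) -> TrainResult:
    """Fit ``model`` and return it loaded with the best-validation epoch.

    Raises ``RuntimeError`` on divergence (non-finite loss). With no
    validation data the best epoch is judged on training accuracy.
    """
    x_train, y_train = train_data
    present = set(np.unique(y_train).tolist())
    if present != set(range(len(LABELS))):
        missing = [LABELS[i] for i in range(len(LABELS)) if i not in present]
        raise ValueError(f"training split is missing classes: {missing}")
    rng = np.random.default_rng(config.seed)
    optimiser = Adam(model, lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": [],
    }
    step_losses: list[float] = []
    best = (-1.0, np.inf, -1)  # (val_acc, val_loss, epoch)
    best_state = model.state_dict()
    model.train()
    for epoch in range(config.epochs):
        order = np.arange(len(x_train))
        if not config.freeze:
            rng.shuffle(order)
        epoch_loss, epoch_correct = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model(xb)
            loss, dlogits = cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1} "
                    f"(lr={config.learning_rate}); lower the learning rate"
                )
            step_losses.append(loss)
            epoch_loss += loss * len(xb)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
            if not config.freeze:
                model.zero_grad()
                model.backward(dlogits)
                optimiser.step()
        history["train_loss"].append(epoch_loss / len(order))
        history["train_accuracy"].append(epoch_correct / len(order))
        if val_data is not None and len(val_data[0]):
            val_loss, val_acc = _evaluate(model, val_data[0], val_data[1], config.batch_size)
        else:
            val_loss, val_acc = history["train_loss"][-1], history["train_accuracy"][-1]
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        if (val_acc, -val_loss) > (best[0], -best[1]):
            best = (val_acc, val_loss, epoch)
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    model.eval()
    return TrainResult(
        model=model,
        history=history,
        step_losses=step_losses,
        best_epoch=best[2],
        best_val_accuracy=best[0],
    )


def predict(model: Module, image: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one RGB image (must already be 224×224).

    Returns (label, probabilities); the probabilities sum to 1 and ties
    resolve to the lowest class index (healthy < unhealthy < none).
    """
    image = np.asarray(image)
    if image.shape[:2] != (NET_INPUT_SIZE, NET_INPUT_SIZE) or image.ndim != 3:
        raise ValueError(
            f"expected a {NET_INPUT_SIZE}×{NET_INPUT_SIZE}×3 image, got {image.shape}"
        )
    model.eval()
    logits = model(_prepare(image)[None])
    probs = softmax(logits)[0]
    return LABELS[int(np.argmax(logits[0]))], probs


def save_checkpoint(model: Module, path: str | Path) -> None:
    """Persist parameters and buffers as an .npz archive."""
    state = model.state_dict()
    np.savez(path, **state)


def load_checkpoint(model: Module, path: str | Path) -> Module:
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model
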
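"""Cross-entropy training of the hybrid network on labeled data blocks.

The loss is the per-voxel binary cross-entropy of the brain-class
probability, evaluated on the *middle* output slice only — a block carries
only the middle slice's label.  Optimization uses Adam at a constant
learning rate (default 1e-4, batch size 20, 50 epochs).  All randomness
(shuffling, weight init) flows from the config seed, so a fixed seed on a
fixed machine reproduces the loss history exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datablock import DataBlock
from .model import HCNet, HCNetConfig, save_checkpoint
from .nn import Adam, softmax

__all__ = ["TrainConfig", "TrainHistory", "cross_entropy_loss", "train"]

_EPS = 1e-7  # probability clamp inside the log


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 20
    epochs: int = 50
    seed: int = 0
    checkpoint_dir: str | None = None
    validation_fraction: float = 0.0  # volume-level split applied by the caller

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be at least 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int | None = None
    best_val_dice: float = -1.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of the brain-class probability.

    ``probabilities`` is ``(N, 2, 3, H, W)`` (loss taken on the middle
    slice) or ``(N, 2, H, W)``; ``labels`` is binary ``(N, H, W)``.
    Probabilities are clamped to ``[eps, 1-eps]`` for numerical safety.
    """
    p = np.asarray(probabilities)
    y = np.asarray(labels)
    if p.ndim == 5:
        p1 = p[:, 1, p.shape[2] // 2]
    elif p.ndim == 4:
        p1 = p[:, 1]
    else:
        raise ValueError(f"expected rank-4 or rank-5 probabilities, got {p.shape}")
    if y.shape != p1.shape:
        raise ValueError(f"label shape {y.shape} does not match slice shape {p1.shape}")
    p1 = np.clip(p1.astype(np.float64), _EPS, 1.0 - _EPS)
    y = y.astype(np.float64)
    return float(np.mean(-(y * np.log(p1) + (1.0 - y) * np.log(1.0 - p1))))


def _batch_arrays(blocks: Sequence[DataBlock], idx, dtype=np.float32):
    x = np.stack([blocks[i].planes for i in idx]).astype(dtype)[:, None]
    y = np.stack([blocks[i].label for i in idx]).astype(dtype)
    return x, y


def _loss_and_logit_grad(logits: np.ndarray, labels: np.ndarray):
    """Softmax cross-entropy on the middle slice; returns (loss, dlogits)."""
    n, _, d, h, w = logits.shape
    mid = d // 2
    probs_mid = softmax(logits[:, :, mid].astype(np.float64), axis=1)
    p1 = np.clip(probs_mid[:, 1], _EPS, 1.0 - _EPS)
    y = labels.astype(np.float64)
    loss = float(np.mean(-(y * np.log(p1) + (1.0 - y) * np.log(1.0 - p1))))
    dlogits = np.zeros_like(logits)
    n_vox = y.size
    # d(loss)/d(logit) = (p - onehot(y)) / n_vox, middle slice only
    target = np.stack([1.0 - y, y], axis=1)
    dlogits[:, :, mid] = ((probs_mid - target) / n_vox).astype(logits.dtype)
    return loss, dlogits


def _middle_slice_dice(logits: np.ndarray, labels: np.ndarray):
    pred = logits[:, 1, logits.shape[2] // 2] >= logits[:, 0, logits.shape[2] // 2]
    t = labels.astype(bool)
    tp = np.count_nonzero(pred & t)
    fp = np.count_nonzero(pred & ~t)
    fn = np.count_nonzero(~pred & t)
    return tp, fp, fn


def train(
    dataset: Sequence[DataBlock],
    val: Sequence[DataBlock] | None,
    config: TrainConfig,
    model_config: HCNetConfig | None = None,
    model: HCNet | None = None,
    log=None,
) -> tuple[HCNet, TrainHistory]:
    """Mini-batch training; returns the model and its history.

    Validation Dice is the micro-averaged (confusion counts pooled over all
    validation blocks) middle-slice Dice per epoch; the best-validation
    state is restored at the end and saved when ``checkpoint_dir`` is set.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    if any(b.label is None for b in dataset):
        raise ValueError("training blocks must carry labels")
    h, w = dataset[0].planes.shape[1:]
    if model is None:
        if model_config is None:
            model_config = HCNetConfig(cube_size=h, seed=config.seed)
        model = HCNet(model_config)

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_state = None
    n = len(dataset)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x, y = _batch_arrays(dataset, idx)
            logits = model.forward_logits(x, training=True)
            loss, dlogits = _loss_and_logit_grad(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}: {loss}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))

        if val:
            tp = fp = fn = 0
            for start in range(0, len(val), config.batch_size):
                idx = range(start, min(start + config.batch_size, len(val)))
                x, y = _batch_arrays(val, idx)
                logits = model.forward_logits(x, training=False)
                dtp, dfp, dfn = _middle_slice_dice(logits, y)
                tp += dtp
                fp += dfp
                fn += dfn
            vdice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
            history.val_dice.append(float(vdice))
            if vdice > history.best_val_dice:
                history.best_val_dice = float(vdice)
                history.best_epoch = epoch + 1
                best_state = {k: v.copy() for k, v in model.state_items()}
        if log is not None:
            log(epoch + 1, history)

    if best_state is not None:
        model.load_state(best_state)
    if config.checkpoint_dir is not None:
        out = Path(config.checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out / "checkpoint.npz",
                        extra={"train_config": asdict(config)})
        history.to_json(out / "history.json")
    return model, history
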
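"""Seeded training loop for the multi-task U-Net."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..patches import AugmentationPolicy, PatchSample, augment
from .losses import LossConfig, multitask_loss
from .optim import Adam
from .tensor import Tensor
from .unet import UNet3D


@dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    patience: int | None = None  # early stop on validation loss
    augmentation: AugmentationPolicy | None = None
    grad_clip_norm: float | None = 10.0  # global-norm clipping
    lr_schedule: str = "cosine"  # constant | cosine (floor at 0.1x)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "constant" or self.epochs <= 1:
            return self.learning_rate
        frac = 0.5 * (1 + np.cos(np.pi * epoch / max(self.epochs - 1, 1)))
        return self.learning_rate * (0.1 + 0.9 * frac)


def _to_batch(samples: list[PatchSample]) -> tuple[Tensor, Tensor, Tensor]:
    imgs = np.stack([s.image_patch for s in samples])[..., None]
    masks = np.stack([s.mask_patch for s in samples]).astype(np.float32)[..., None]
    labels = np.array([[s.label] for s in samples], np.float32)
    return Tensor(imgs), Tensor(masks), Tensor(labels)


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _epoch_pass(model, samples, loss_cfg, train_cfg, optimizer, rng, training):
    order = rng.permutation(len(samples)) if training else np.arange(len(samples))
    losses, breakdowns = [], []
    bs = train_cfg.batch_size
    for start in range(0, len(samples), bs):
        batch = [samples[i] for i in order[start : start + bs]]
        if training and train_cfg.augmentation is not None:
            batch = [augment(s, train_cfg.augmentation) for s in batch]
        x, m, y = _to_batch(batch)
        seg, aux = model(x)
        total, terms = multitask_loss(seg, aux, m, y, loss_cfg)
        if not np.isfinite(total.item()):
            raise RuntimeError(
                f"training diverged: non-finite loss {total.item()} (terms {terms})"
            )
        if training:
            model.zero_grad()
            total.backward()
            if train_cfg.grad_clip_norm is not None:
                _clip_grad_norm(model.parameters(), train_cfg.grad_clip_norm)
            optimizer.step()
        losses.append(total.item())
        breakdowns.append(terms)
    mean_terms = {
        k: float(np.mean([b[k] for b in breakdowns])) for k in breakdowns[0]
    }
    return float(np.mean(losses)), mean_terms


def train(
    model: UNet3D,
    train_samples: list[PatchSample],
    val_samples: list[PatchSample],
    train_cfg: TrainConfig,
    loss_cfg: LossConfig | None = None,
) -> tuple[UNet3D, pd.DataFrame]:
    """Train with Adam; returns the model restored to its best-validation
    state and a per-epoch history (train/val losses + per-term breakdown)."""
    loss_cfg = loss_cfg or LossConfig()
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rows = []
    best_val = np.inf
    best_state = model.state_dict()
    bad_epochs = 0
    for epoch in range(train_cfg.epochs):
        optimizer.lr = train_cfg.lr_at(epoch)
        model.train()
        tr_loss, tr_terms = _epoch_pass(
            model, train_samples, loss_cfg, train_cfg, optimizer, rng, True
        )
        row = {"epoch": epoch, "train_loss": tr_loss}
        row.update({f"train_{k}": v for k, v in tr_terms.items()})
        if val_samples:
            model.eval()
            val_loss, _ = _epoch_pass(
                model, val_samples, loss_cfg, train_cfg, optimizer, rng, False
            )
            row["val_loss"] = val_loss
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = model.state_dict()
                bad_epochs = 0
            else:
                bad_epochs += 1
        rows.append(row)
        if (
            train_cfg.patience is not None
            and val_samples
            and bad_epochs > train_cfg.patience
        ):
            break
    if val_samples:
        model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(rows)
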
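"""Segmentation and auxiliary-classification losses.

Segmentation loss = weighted sum of soft Dice, Tversky focal, and voxel
cross-entropy terms; auxiliary loss = binary cross-entropy of the
patch-level classifier heads. When the auxiliary term is enabled the total
is the *average* of segmentation and classifier losses.

The soft Dice term is the alpha = beta = 0.5, gamma = 1 member of the
Tversky focal family, so the algebraic identity Tversky(0.5, 0.5, 1) = Dice
holds exactly, smoothing included. Both use the conventional smooth = 1
stabilizer, which also keeps all-zero-target patches (the frequent case
under skeleton sampling) informative: their loss falls toward 0 as
false-positive mass is suppressed instead of saturating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .tensor import Tensor

SMOOTH = 1.0  # the conventional smooth=1 Dice/Tversky stabilizer
BCE_EPS = 1e-6


@dataclass
class LossConfig:
    dice_weight: float = 1.0
    tversky_focal_weight: float = 1.0
    cross_entropy_weight: float = 1.0
    tversky_alpha: float = 0.3  # false-positive weight
    tversky_beta: float = 0.7  # false-negative weight
    focal_gamma: float = 4.0 / 3.0
    aux_enabled: bool = True

    def __post_init__(self):
        ws = (self.dice_weight, self.tversky_focal_weight, self.cross_entropy_weight)
        if any(w < 0 for w in ws) or not any(w > 0 for w in ws):
            raise ValueError("segmentation term weights must be >= 0 with at least one > 0")
        if not (0 <= self.tversky_alpha <= 1 and 0 <= self.tversky_beta <= 1):
            raise ValueError("tversky alpha/beta must lie in [0, 1]")
        if self.focal_gamma < 0:
            raise ValueError("focal gamma must be >= 0")


def _spatial_axes(t: Tensor) -> tuple[int, ...]:
    return tuple(range(1, len(t.shape)))


def tversky_index(p: Tensor, g: Tensor, alpha: float, beta: float) -> Tensor:
    """Per-sample smoothed Tversky index; reduces over all non-batch axes."""
    axes = _spatial_axes(p)
    tp = (p * g).sum(axis=axes)
    fp = (p * (1.0 - g)).sum(axis=axes)
    fn = ((1.0 - p) * g).sum(axis=axes)
    return (tp + SMOOTH) / (tp + alpha * fp + beta * fn + SMOOTH)


def tversky_focal_loss(p: Tensor, g: Tensor, alpha: float, beta: float, gamma: float) -> Tensor:
    return ((1.0 - tversky_index(p, g, alpha, beta)) ** gamma).mean()


def soft_dice_loss(p: Tensor, g: Tensor) -> Tensor:
    """1 - smoothed Dice, written as Tversky(0.5, 0.5); both-empty targets
    give loss 0 through the smoothing term."""
    return tversky_focal_loss(p, g, 0.5, 0.5, 1.0)


def bce_loss(p: Tensor, t: Tensor) -> Tensor:
    """Binary cross-entropy on probabilities, clamped away from {0,1} by an
    affine squeeze so gradients stay finite."""
    pc = p * (1.0 - 2.0 * BCE_EPS) + BCE_EPS
    ll = t * T.log(pc) + (1.0 - t) * T.log(1.0 - pc)
    return -ll.mean()


def segmentation_loss(p: Tensor, g: Tensor, cfg: LossConfig) -> tuple[Tensor, dict]:
    terms: dict[str, float] = {}
    total = None
    if cfg.dice_weight > 0:
        t = soft_dice_loss(p, g)
        terms["dice"] = t.item()
        total = cfg.dice_weight * t if total is None else total + cfg.dice_weight * t
    if cfg.tversky_focal_weight > 0:
        t = tversky_focal_loss(p, g, cfg.tversky_alpha, cfg.tversky_beta, cfg.focal_gamma)
        terms["tversky_focal"] = t.item()
        total = cfg.tversky_focal_weight * t if total is None else total + cfg.tversky_focal_weight * t
    if cfg.cross_entropy_weight > 0:
        t = bce_loss(p, g)
        terms["cross_entropy"] = t.item()
        total = cfg.cross_entropy_weight * t if total is None else total + cfg.cross_entropy_weight * t
    return total, terms


def multitask_loss(
    seg_prob: Tensor,
    aux_probs: list[Tensor],
    target_mask: Tensor,
    target_labels: Tensor,
    cfg: LossConfig,
) -> tuple[Tensor, dict]:
    """Total loss for a batch: mean(seg_loss, aux_loss) when auxiliary heads
    are enabled, else seg_loss alone. Returns (scalar tensor, breakdown)."""
    seg, terms = segmentation_loss(seg_prob, target_mask, cfg)
    if cfg.aux_enabled and aux_probs:
        aux_terms = [bce_loss(a, target_labels) for a in aux_probs]
        aux = aux_terms[0]
        for t in aux_terms[1:]:
            aux = aux + t
        aux = aux * (1.0 / len(aux_terms))
        terms["aux_bce"] = aux.item()
        total = (seg + aux) * 0.5
    else:
        terms["aux_bce"] = 0.0
        total = seg
    terms["segmentation"] = seg.item()
    terms["total"] = total.item()
    return total, terms


def compute_loss(
    seg_probability: np.ndarray,
    target_mask: np.ndarray,
    target_label: int | np.ndarray,
    cfg: LossConfig | None = None,
    aux_probability: float | np.ndarray | None = None,
) -> tuple[float, dict]:
    """Numpy-facing loss evaluation for a single patch or a batch.

    Raises if the patch label contradicts mask occupancy."""
    cfg = cfg or LossConfig()
    p = np.asarray(seg_probability, np.float32)
    g = np.asarray(target_mask, np.float32)
    if p.ndim == 3:
        p, g = p[None], g[None]
    labels = np.atleast_1d(np.asarray(target_label, np.float32))
    occupancy = g.reshape(len(g), -1).any(axis=1)
    if not np.array_equal(occupancy.astype(int), labels.astype(int)):
        raise ValueError("target_label inconsistent with target_mask occupancy")
    aux = []
    if aux_probability is not None:
        aux = [Tensor(np.atleast_1d(np.asarray(aux_probability, np.float32)).reshape(-1, 1))]
    total, terms = multitask_loss(
        Tensor(p), aux, Tensor(g), Tensor(labels.reshape(-1, 1)), cfg
    )
    return total.item(), terms
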
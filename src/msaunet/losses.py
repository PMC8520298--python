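"""Compound segmentation loss: weighted binary cross-entropy + Dice.

The total loss is ``alpha * L_bce + beta * L_dcl`` with defaults
``alpha = 0.5``, ``beta = 1.0``. Functions accept plain numpy arrays
(returning floats, computed in float64) or autograd :class:`Tensor`
inputs (returning a differentiable scalar tensor), so the same formulas
drive both evaluation and training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["LossWeights", "bce_loss", "dice_loss", "total_loss", "binarize",
           "EPS_LOG", "EPS_DICE"]

EPS_LOG = 1e-7    # probability clamp before taking logs
EPS_DICE = 1e-6   # Dice smoothing, guards empty target + empty prediction


@dataclass(frozen=True)
class LossWeights:
    """Weights balancing cross-entropy (alpha) and Dice (beta)."""

    alpha: float = 0.5
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha + self.beta == 0:
            raise ValueError("at least one loss weight must be positive")


def _check_shapes(y, p):
    ys = y.shape if hasattr(y, "shape") else np.shape(y)
    ps = p.shape if hasattr(p, "shape") else np.shape(p)
    if ys != ps:
        raise ValueError(f"target shape {ys} does not match prediction shape {ps}")


def _prepare(y, p):
    """Normalize inputs: Tensor stays a Tensor, arrays become float64."""
    _check_shapes(y, p)
    if isinstance(p, Tensor):
        y_data = y.data if isinstance(y, Tensor) else np.asarray(y)
        return np.asarray(y_data, dtype=p.data.dtype), p
    return np.asarray(y, dtype=np.float64), np.asarray(p, dtype=np.float64)


def bce_loss(y, p, eps: float = EPS_LOG):
    """Mean binary cross-entropy, with ``p`` clamped to [eps, 1-eps]."""
    y, p = _prepare(y, p)
    pc = p.clip(eps, 1.0 - eps) if isinstance(p, Tensor) else np.clip(p, eps, 1.0 - eps)
    if isinstance(pc, Tensor):
        loss = -(y * pc.log() + (1.0 - y) * (1.0 - pc).log())
        return loss.mean()
    return float(np.mean(-y * np.log(pc) - (1.0 - y) * np.log(1.0 - pc)))


def dice_loss(y, p, smooth: float = EPS_DICE):
    """Soft Dice loss: ``1 - 2*sum(p*y) / (sum(y) + sum(p))``, smoothed."""
    y, p = _prepare(y, p)
    inter = (p * y).sum()
    denom = y.sum() + p.sum()
    out = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return out if isinstance(p, Tensor) else float(out)


def total_loss(y, p, weights: LossWeights | None = None):
    """Weighted compound loss ``alpha * bce + beta * dice``."""
    w = weights or LossWeights()
    out = w.alpha * bce_loss(y, p) + w.beta * dice_loss(y, p)
    return out if isinstance(p, Tensor) else float(out)


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: 1 where ``p`` is strictly above."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return (np.asarray(p) > threshold).astype(np.uint8)
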
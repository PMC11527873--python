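"""Focal Tversky loss for extremely class-imbalanced binary segmentation.

The Tversky index generalises Dice by weighting false negatives and false
positives asymmetrically:

    TI = (TP + s) / (TP + alpha * FN + beta * FP + s)

with soft counts TP = sum(p*g), FP = sum(p*(1-g)), FN = sum((1-p)*g) over
the probability map p and binary target g, and a small stabiliser s.  The
focal loss raises the shortfall to an exponent:

    L = (1 - TI) ** gamma

which accentuates hard, small targets.  Defaults (alpha=0.7, beta=0.3,
gamma=4/3) follow the loss's original formulation; passing ``gamma=3/4``
gives the reciprocal-exponent form some implementations use.  The loss is
computed per image and averaged over the batch so that images with larger
targets cannot dominate a minibatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 4.0 / 3.0
    smooth: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.smooth <= 0:
            raise ValueError("smooth must be > 0")


def tversky_index(tp, fn, fp, cfg: LossConfig = LossConfig()):
    """Tversky index from (possibly soft) confusion counts.

    Works on plain numbers, arrays and autodiff tensors alike.
    """
    return (tp + cfg.smooth) / (tp + cfg.alpha * fn + cfg.beta * fp + cfg.smooth)


def focal_tversky_loss(pred, truth, cfg: LossConfig = LossConfig()):
    """Mean per-image focal Tversky loss of a batch.

    ``pred`` is a probability map (values in [0, 1]); ``truth`` a binary
    mask of the same shape.  Both may be NumPy arrays or Tensors; the
    leading axis is the batch.  Returns a scalar Tensor when ``pred`` is a
    Tensor (differentiable), otherwise a float.
    """
    is_tensor = isinstance(pred, Tensor)
    p = pred if is_tensor else Tensor(np.asarray(pred, dtype=np.float32))
    g_arr = truth.data if isinstance(truth, Tensor) else np.asarray(truth)
    g = Tensor(g_arr.astype(np.float32))
    if tuple(p.shape) != tuple(g.shape):
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {g.shape}")
    if p.ndim < 2:
        raise ValueError("expected a batched input (batch axis first)")
    axes = tuple(range(1, p.ndim))
    tp = (p * g).sum(axis=axes)
    fp = (p * (1.0 - g)).sum(axis=axes)
    fn = ((1.0 - p) * g).sum(axis=axes)
    ti = tversky_index(tp, fn, fp, cfg)
    loss = ((1.0 - ti) ** cfg.gamma).mean()
    return loss if is_tensor else float(loss.data)


__all__ = ["LossConfig", "tversky_index", "focal_tversky_loss"]
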
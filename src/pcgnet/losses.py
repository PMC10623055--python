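"""Segmentation and contrastive losses.

Two losses live here:

* the focal-dice loss, a class-imbalance-aware compound of a soft multi-class
  dice term and a focal cross-entropy term.  The dice term turns pixel-wise
  labelling into matching per-class soft confusion counts, so tiny structures
  (well under 1% of pixels) still contribute a full unit of loss; the focal
  term re-weights pixels by (1-p)^2 so easy background pixels fade out.

      l_DF = l_DSC + alpha * l_Focal
      l_DSC = M - sum_m TP(m) / (TP(m) + beta FN(m) + eta FP(m))
      l_Focal = -(1/N) sum_m sum_n g_n(m) (1 - p_n(m))^2 log p_n(m)

  with soft counts TP(m)=sum p g, FN(m)=sum g(1-p), FP(m)=sum (1-g)p, taken
  over all M classes including background.  Defaults alpha=2, beta=eta=1.

* the Siamese negative-cosine loss with stop-gradient used for contrastive
  pretraining: L = S(p1, sg(z2))/2 + S(p2, sg(z1))/2 where S is negative
  cosine similarity and sg blocks gradient flow, which is what prevents the
  twin branches from collapsing to a constant embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as np

from .nn import stop_gradient


@dataclass
class FocalDiceConfig:
    alpha: float = 2.0  # dice/focal trade-off
    beta: float = 1.0  # false-negative penalty
    eta: float = 1.0  # false-positive penalty
    eps: float = 1e-8  # probability clamp before log; also guards 0/0 dice
    include_background: bool = True

    def __post_init__(self):
        if self.alpha < 0 or self.beta <= 0 or self.eta <= 0:
            raise ValueError("require alpha >= 0 and beta, eta > 0")


def soft_confusion(probs, onehot):
    """Per-class soft confusion counts from (N, M) probabilities and one-hot truth.

    Returns (TP, FN, FP), each a length-M vector.  TP(m) + FN(m) equals the
    true pixel count of class m by construction.
    """
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs onehot {onehot.shape}")
    tp = np.sum(probs * onehot, axis=0)
    fn = np.sum(onehot * (1.0 - probs), axis=0)
    fp = np.sum((1.0 - onehot) * probs, axis=0)
    return tp, fn, fp


def focal_dice_loss(probs, onehot, cfg: FocalDiceConfig = FocalDiceConfig()):
    """Focal-dice loss for flat (N, M) probabilities and one-hot labels."""
    if probs.size == 0:
        raise ValueError("focal_dice_loss: empty input")
    if probs.shape != onehot.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs onehot {onehot.shape}")
    n = probs.shape[0]
    tp, fn, fp = soft_confusion(probs, onehot)
    if not cfg.include_background:
        tp, fn, fp = tp[1:], fn[1:], fp[1:]
        m = probs.shape[1] - 1
    else:
        m = probs.shape[1]
    dice = np.sum(tp / (tp + cfg.beta * fn + cfg.eta * fp + cfg.eps))
    l_dsc = m - dice
    p = np.clip(probs, cfg.eps, 1.0)
    focal = onehot * (1.0 - p) ** 2 * np.log(p)
    if not cfg.include_background:
        focal = focal[:, 1:]
    l_focal = -np.sum(focal) / n
    return l_dsc + cfg.alpha * l_focal


def negative_cosine(p, z):
    """Negative cosine similarity between two nonzero vectors (in [-1, 1])."""
    from autograd.tracer import getval

    pn = np.sqrt(np.sum(p * p))
    zn = np.sqrt(np.sum(z * z))
    if float(getval(pn)) == 0.0 or float(getval(zn)) == 0.0:
        raise ValueError("negative_cosine: zero-norm vector")
    return -np.sum((p / pn) * (z / zn))


def negative_cosine_batch(p, z, eps=1e-12):
    """Row-wise mean negative cosine for (N, D) batches."""
    pn = p / np.sqrt(np.sum(p * p, axis=1, keepdims=True) + eps)
    zn = z / np.sqrt(np.sum(z * z, axis=1, keepdims=True) + eps)
    return -np.mean(np.sum(pn * zn, axis=1))


def siamese_loss(p1, z1, p2, z2):
    """Symmetric stop-gradient Siamese loss.

    Gradient flows only through the predictor outputs p1, p2; the projector
    outputs z1, z2 are treated as constants.  Accepts vectors or (N, D)
    batches.
    """
    z1c = stop_gradient(z1)
    z2c = stop_gradient(z2)
    if p1.ndim == 1:
        return 0.5 * negative_cosine(p1, z2c) + 0.5 * negative_cosine(p2, z1c)
    return 0.5 * negative_cosine_batch(p1, z2c) + 0.5 * negative_cosine_batch(p2, z1c)


def labels_to_onehot(labels, num_classes):
    """Integer (..., ) label array to float one-hot (..., M)."""
    import numpy as onp

    flat = onp.asarray(labels).reshape(-1)
    if flat.min() < 0 or flat.max() >= num_classes:
        raise ValueError(
            f"label values outside [0, {num_classes}): found [{flat.min()}, {flat.max()}]"
        )
    eye = onp.eye(num_classes, dtype=onp.float32)
    return eye[flat].reshape(*onp.asarray(labels).shape, num_classes)
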
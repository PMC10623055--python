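"""Training procedures: Siamese contrastive pretraining and supervised
fine-tuning with deep supervision.

Pretraining consumes *images only*: every batch draws two independent random
views of each image from the augmentation cluster, runs both through the
parallel encoder, pools the deepest features, and optimises the stop-gradient
Siamese loss over a projector/predictor MLP head with SGD (momentum 0.9,
cosine-decayed, linearly scaled learning rate).  After training the MLP heads
are discarded and the encoder weights can be transferred into the full
segmentation network.

Supervised training optimises the deep-supervised focal-dice objective with
Adam and a polynomial learning-rate decay ("poly", power 0.9), tracking
validation mean DSC per epoch and keeping the best checkpoint.  Given a seed
the whole procedure is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as onp

import autograd.numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from . import nn
from .decoder import ModelConfig, pcgnet_forward, predict_label
from .encoder import EncoderConfig, encode, init_encoder
from .losses import FocalDiceConfig, focal_dice_loss, labels_to_onehot, siamese_loss
from .metrics import dsc
from .phantoms import PhantomSample, contrastive_view

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# optimisers and schedules
# ---------------------------------------------------------------------------


def cosine_lr(base_lr, epoch, total_epochs):
    return base_lr * 0.5 * (1.0 + onp.cos(onp.pi * epoch / total_epochs))


def poly_lr(base_lr, epoch, total_epochs, power=0.9):
    return base_lr * (1.0 - epoch / total_epochs) ** power


class SGD:
    """SGD with momentum and decoupled-from-schedule weight decay (classic
    L2-in-gradient form)."""

    def __init__(self, momentum=0.9, weight_decay=1e-4):
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.v = None

    def step(self, w_flat, g_flat, lr):
        g = g_flat + self.weight_decay * w_flat
        if self.v is None:
            self.v = onp.zeros_like(w_flat)
        self.v = self.momentum * self.v + g
        return w_flat - lr * self.v


class Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8, weight_decay=1e-4):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = None
        self.v = None
        self.t = 0

    def step(self, w_flat, g_flat, lr):
        g = g_flat + self.weight_decay * w_flat
        if self.m is None:
            self.m = onp.zeros_like(w_flat)
            self.v = onp.zeros_like(w_flat)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g * g
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return w_flat - lr * mhat / (onp.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class PretrainConfig:
    """Contrastive pretraining protocol (full-scale defaults)."""

    epochs: int = 50
    batch_size: int = 32
    base_lr: float = 0.05  # linearly scaled: lr = base_lr * batch / 256
    weight_decay: float = 1e-4
    momentum: float = 0.9
    projector_dim: int = 128
    projector_hidden: int = 256
    predictor_hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @property
    def lr(self):
        return self.base_lr * self.batch_size / 256.0


@dataclass
class TrainConfig:
    """Supervised fine-tuning protocol (full-scale defaults)."""

    epochs: int = 150
    batch_size: int = 32
    lr: float = 1e-4
    weight_decay: float = 1e-4
    poly_power: float = 0.9
    bn_momentum: float = 0.9
    seed: int = 0
    augment: bool = False
    focal_dice: FocalDiceConfig = field(default_factory=FocalDiceConfig)


def desk_pretrain_config(**overrides) -> PretrainConfig:
    """Scaled-down protocol for single-CPU runs.

    The linear-scaling rule is re-anchored so the *effective* learning rate
    stays at 0.05: a run of well under a hundred optimisation steps makes no
    progress at the 256-sample-anchored rate (verified by pilot runs where
    the Siamese loss stayed near zero).
    """
    base = dict(
        epochs=10,
        batch_size=4,  # small batches buy optimisation steps, as in fine-tuning
        base_lr=0.05 * 256 / 4,  # effective lr = 0.05 at the desk batch size
        projector_dim=32,
        projector_hidden=64,
        predictor_hidden=16,
    )
    base.update(overrides)
    return PretrainConfig(**base)


def desk_train_config(**overrides) -> TrainConfig:
    """Scaled-down protocol for single-CPU runs.

    Small batches buy optimisation steps (the scaled runs see only a few
    hundred of them), the learning rate is raised accordingly, and the
    batch-norm momentum is lowered so running statistics settle within the
    short schedule.
    """
    base = dict(epochs=15, batch_size=4, lr=5e-3, bn_momentum=0.8)
    base.update(overrides)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def _stack_images(samples) -> onp.ndarray:
    imgs = [s.image if hasattr(s, "image") else onp.asarray(s) for s in samples]
    return onp.stack(imgs).astype(nn.DTYPE)[:, None, :, :]


def _stack_labels(samples) -> onp.ndarray:
    labels = []
    for s in samples:
        labels.append(s.require_label() if isinstance(s, PhantomSample) else onp.asarray(s))
    return onp.stack(labels).astype(onp.int64)


# ---------------------------------------------------------------------------
# contrastive pretraining
# ---------------------------------------------------------------------------


def _init_mlp_head(rng, d_in, cfg: PretrainConfig):
    return {
        "proj": [
            {"lin": nn.linear_init(rng, cfg.projector_hidden, d_in), "bn": _vec_bn(cfg.projector_hidden)},
            {"lin": nn.linear_init(rng, cfg.projector_hidden, cfg.projector_hidden), "bn": _vec_bn(cfg.projector_hidden)},
            {"lin": nn.linear_init(rng, cfg.projector_dim, cfg.projector_hidden), "bn": _vec_bn(cfg.projector_dim)},
        ],
        "pred": [
            {"lin": nn.linear_init(rng, cfg.predictor_hidden, cfg.projector_dim), "bn": _vec_bn(cfg.predictor_hidden)},
            {"lin": nn.linear_init(rng, cfg.projector_dim, cfg.predictor_hidden)},
        ],
    }


def _vec_bn(d):
    return {"gamma": onp.ones(d, dtype=nn.DTYPE), "beta": onp.zeros(d, dtype=nn.DTYPE)}


def _mlp_forward(head, x, bn, training):
    h = x
    for i, layer in enumerate(head["proj"]):
        h = nn.linear(h, layer["lin"]["w"], layer["lin"]["b"])
        h = nn.batch_norm_vec(h, layer["bn"]["gamma"], layer["bn"]["beta"], bn, f"proj{i}", training)
        if i < len(head["proj"]) - 1:
            h = nn.relu(h)
    z = h
    p = z
    for i, layer in enumerate(head["pred"]):
        p = nn.linear(p, layer["lin"]["w"], layer["lin"]["b"])
        if "bn" in layer:
            p = nn.batch_norm_vec(p, layer["bn"]["gamma"], layer["bn"]["beta"], bn, f"pred{i}", training)
            p = nn.relu(p)
    return z, p


def _encode_pooled(enc_params, images, enc_cfg, bn, training):
    pyramid = encode(enc_params, images, enc_cfg, bn, training)
    c4, g4 = pyramid[-1]
    feats = [f for f in (c4, g4) if f is not None]
    pooled = np.concatenate([nn.global_avg_pool(f) for f in feats], axis=1)
    return pooled


def pretrain(images, cfg: PretrainConfig, enc_cfg: EncoderConfig | None = None):
    """Contrastive pretraining of the parallel encoder on unlabeled images.

    ``images`` is an (N, H, W) array or a list of images/unlabeled samples.
    Returns ``(encoder_weights, result)`` where result carries the per-epoch
    mean loss trace and an embedding-collapse diagnostic (per-dimension std
    of the L2-normalised projector output on the final pass).
    """
    if len(images) == 0:
        raise ValueError("pretrain: empty image set")
    x_all = _stack_images(images)
    n, _, h, w = x_all.shape
    enc_cfg = enc_cfg or EncoderConfig(image_size=h)
    rng = onp.random.default_rng(cfg.seed)
    enc_params = init_encoder(rng, enc_cfg, branches=("cnn", "gat"))
    d_pool = enc_cfg.stage_channels[-1] * 2
    head = _init_mlp_head(rng, d_pool, cfg)
    params = {"enc": enc_params, "head": head}
    bn = nn.BNState()

    def loss_fn(p, v1, v2):
        z1, p1 = _mlp_forward(p["head"], _encode_pooled(p["enc"], v1, enc_cfg, bn, True), bn, True)
        z2, p2 = _mlp_forward(p["head"], _encode_pooled(p["enc"], v2, enc_cfg, bn, True), bn, True)
        return siamese_loss(p1, z1, p2, z2)

    vg = value_and_grad(loss_fn)
    flat, unflatten = flatten(params)
    opt = SGD(momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    trace = []
    for epoch in range(cfg.epochs):
        lr = cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = onp.random.default_rng(cfg.seed + 1000 + epoch).permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue  # Siamese batch statistics need at least 2 samples
            vrng = onp.random.default_rng(cfg.seed + 7919 * epoch + start)
            v1 = onp.stack([contrastive_view(x_all[i, 0], vrng) for i in idx])[:, None]
            v2 = onp.stack([contrastive_view(x_all[i, 0], vrng) for i in idx])[:, None]
            params = unflatten(flat)
            val, g = vg(params, v1.astype(nn.DTYPE), v2.astype(nn.DTYPE))
            gflat, _ = flatten(g)
            flat = opt.step(flat, gflat, lr)
            losses.append(float(val))
        trace.append(float(onp.mean(losses)))
        logger.info("pretrain epoch %d: loss=%.4f lr=%.5f", epoch + 1, trace[-1], lr)

    params = unflatten(flat)
    # collapse diagnostic on a final deterministic pass
    take = min(n, 2 * cfg.batch_size)
    z, _ = _mlp_forward(
        params["head"], _encode_pooled(params["enc"], x_all[:take], enc_cfg, bn, True), bn, True
    )
    z = onp.asarray(z)
    z = z / onp.linalg.norm(z, axis=1, keepdims=True).clip(1e-12)
    result = {
        "loss_trace": trace,
        "z_std": float(onp.std(z, axis=0).mean()),
        "bn_state": bn,
        "encoder_config": enc_cfg,
    }
    return params["enc"], result


def transfer(encoder_weights, model_params):
    """Copy pretrained encoder tensors into a freshly initialised model.

    Returns ``(params, manifest)``; the manifest partitions every parameter
    path into transferred vs freshly initialised.  Shape mismatches raise,
    listing the offending tensors.
    """
    target = model_params["encoder"]
    src_leaves = dict(nn.tree_leaves(encoder_weights))
    dst_leaves = dict(nn.tree_leaves(target))
    missing = sorted(set(dst_leaves) - set(src_leaves))
    bad = sorted(
        p for p in set(src_leaves) & set(dst_leaves) if src_leaves[p].shape != dst_leaves[p].shape
    )
    if missing or bad:
        raise ValueError(
            "encoder architecture mismatch; missing tensors: "
            f"{missing[:5]}; shape mismatches: "
            + ", ".join(f"{p} {src_leaves[p].shape}->{dst_leaves[p].shape}" for p in bad[:5])
        )

    def copy_into(dst, src):
        for k, v in dst.items() if isinstance(dst, dict) else enumerate(dst):
            if isinstance(v, (dict, list)):
                copy_into(v, src[k])
            else:
                dst[k] = src[k].copy()

    import copy

    params = copy.deepcopy(model_params)
    copy_into(params["encoder"], encoder_weights)
    transferred = [f"encoder/{p}" for p in sorted(dst_leaves)]
    fresh = [p for p, _ in nn.tree_leaves(params) if not p.startswith("encoder/")]
    manifest = {"transferred": transferred, "fresh": fresh}
    return params, manifest


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------


def downsample_labels_presence(labels, stride, num_classes):
    """Label downsampling that preserves small structures.

    Plain stride (nearest-neighbour) sampling deletes any structure smaller
    than the stride, after which the coarse supervision branches only ever
    see false positives for that class and train the network to suppress it —
    the opposite of what deep supervision is for.  Here a low-resolution cell
    takes the label of the *rarest* class present in it (background only if
    nothing else is), so every structure survives at every scale.
    """
    if stride == 1:
        return labels
    n, h, w = labels.shape
    blocks = labels.reshape(n, h // stride, stride, w // stride, stride)
    counts = onp.bincount(labels.ravel(), minlength=num_classes)
    order = [c for c in onp.argsort(counts) if c != 0]  # rarest structures first
    out = onp.zeros((n, h // stride, w // stride), dtype=labels.dtype)
    assigned = onp.zeros(out.shape, dtype=bool)
    for cls in order:
        present = (blocks == cls).any(axis=(2, 4)) & ~assigned
        out[present] = cls
        assigned |= present
    return out


def deep_supervised_loss(prob_maps, labels, num_classes, weights, fd_cfg):
    """Deep supervision: focal-dice at every prediction scale, ground truth
    downsampled by presence-preserving pooling."""
    h = labels.shape[1]
    total = 0.0
    wsum = 0.0
    for pm, wgt in zip(prob_maps, weights[-len(prob_maps) :]):
        stride = h // pm.shape[2]
        gt = downsample_labels_presence(labels, stride, num_classes)
        onehot = labels_to_onehot(gt, num_classes).reshape(-1, num_classes)
        flat = np.reshape(np.transpose(pm, (0, 2, 3, 1)), (-1, num_classes))
        total = total + wgt * focal_dice_loss(flat, onehot, fd_cfg)
        wsum += wgt
    return total / wsum


def validation_mean_dsc(params, bn, model_cfg: ModelConfig, x_val, y_val, batch_size=8):
    """Macro mean DSC over structures 1..M-1, averaged over samples."""
    per_struct = [[] for _ in range(model_cfg.num_classes - 1)]
    for start in range(0, x_val.shape[0], batch_size):
        xb = x_val[start : start + batch_size]
        pred = predict_label(params, xb, model_cfg, bn)
        for i in range(xb.shape[0]):
            for m in range(1, model_cfg.num_classes):
                d, _ = dsc(pred[i] == m, y_val[start + i] == m)
                per_struct[m - 1].append(d)
    means = [float(onp.mean(v)) for v in per_struct]
    return float(onp.mean(means)), means


def train(
    train_samples,
    val_samples,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    init_params=None,
):
    """Supervised training of any ablation variant.

    Returns a dict with the best-validation parameters and batch-norm state,
    the final ones, and a per-epoch trace of training loss and validation
    mean DSC.
    """
    from .decoder import init_model

    x_tr, y_tr = _stack_images(train_samples), _stack_labels(train_samples)
    x_va, y_va = _stack_images(val_samples), _stack_labels(val_samples)
    if int(y_tr.max()) >= model_cfg.num_classes:
        raise ValueError(
            f"labels contain value {int(y_tr.max())} but the model has "
            f"{model_cfg.num_classes} classes"
        )
    rng = onp.random.default_rng(cfg.seed)
    params = init_params if init_params is not None else init_model(rng, model_cfg)
    bn = nn.BNState(momentum=cfg.bn_momentum)
    n = x_tr.shape[0]

    def loss_fn(p, xb, yb):
        probs = pcgnet_forward(p, xb, model_cfg, bn, training=True)
        return deep_supervised_loss(
            probs, yb, model_cfg.num_classes, model_cfg.deep_supervision_weights, cfg.focal_dice
        )

    vg = value_and_grad(loss_fn)
    flat, unflatten = flatten(params)
    opt = Adam(weight_decay=cfg.weight_decay)
    trace = []
    best = {"val_dsc": -1.0, "params": None, "bn": None, "epoch": -1}

    def augment_batch(xb, yb, epoch, start):
        """Paper-style geometric + grayscale augmentation of one minibatch."""
        from .phantoms import augment as augment_sample

        out_x, out_y = [], []
        for i in range(xb.shape[0]):
            s = PhantomSample(image=xb[i, 0], label=yb[i].astype(onp.int16))
            s = augment_sample(
                s,
                ["mirror", ("rotate", {"range": (-15, 15)}),
                 ("translate", {"max_fraction": 0.06}), ("affine", {"jitter": 0.04}),
                 ("gray_float", {"sd": 0.02})],
                seed=cfg.seed + 104729 * epoch + 389 * start + i,
            )
            out_x.append(s.image)
            out_y.append(s.label)
        return (
            onp.stack(out_x)[:, None].astype(nn.DTYPE),
            onp.stack(out_y).astype(onp.int64),
        )

    for epoch in range(cfg.epochs):
        lr = poly_lr(cfg.lr, epoch, cfg.epochs, cfg.poly_power)
        order = onp.random.default_rng(cfg.seed + 5000 + epoch).permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) == 0:
                continue
            xb, yb = x_tr[idx], y_tr[idx]
            if cfg.augment:
                xb, yb = augment_batch(xb, yb, epoch, start)
            params = unflatten(flat)
            val, g = vg(params, xb, yb)
            gflat, _ = flatten(g)
            flat = opt.step(flat, gflat, lr)
            losses.append(float(val))
        params = unflatten(flat)
        vdsc, per_struct = validation_mean_dsc(params, bn, model_cfg, x_va, y_va, cfg.batch_size)
        trace.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(onp.mean(losses)),
                "val_mean_dsc": vdsc,
                "val_dsc_per_structure": per_struct,
                "lr": lr,
            }
        )
        logger.info("epoch %d: loss=%.4f val_dsc=%.4f", epoch + 1, trace[-1]["train_loss"], vdsc)
        if vdsc > best["val_dsc"]:
            best = {"val_dsc": vdsc, "params": params, "bn": bn.copy(), "epoch": epoch + 1}
    return {
        "params": params,
        "bn": bn,
        "best_params": best["params"],
        "best_bn": best["bn"],
        "best_val_dsc": best["val_dsc"],
        "best_epoch": best["epoch"],
        "trace": trace,
    }
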
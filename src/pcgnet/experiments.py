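"""Canned desk-scale experiment protocols.

These fix the study conditions used by the validation suite and the
reproduction script in one place: 64 x 64 phantoms with the default
structure-size spectrum for learnability runs (48 x 48 for pretraining and
smoke checks), the scaled-down level-5 network, and the scaled
supervised/contrastive schedules (see docs/methods.md for the rationale
behind each size).
"""

from __future__ import annotations

import numpy as onp

from autograd import value_and_grad
from autograd.misc import flatten

from . import nn
from .decoder import init_model, pcgnet_forward, tiny_config
from .encoder import EncoderConfig
from .losses import FocalDiceConfig
from .phantoms import PhantomConfig, generate_dataset
from .training import (
    Adam,
    deep_supervised_loss,
    desk_pretrain_config,
    desk_train_config,
    pretrain,
    train,
)

#: Learnability runs use 64 x 64 phantoms: at this size the smallest
#: structure (area fraction 0.002) still rasterises to ~8 pixels, preserving
#: the "very small but representable" regime of the full-scale data.  The
#: cheaper shape/smoke tests run at 48.
IMAGE_SIZE = 64
#: pretraining and the one-step/smoke checks carry no per-pixel labels (or
#: only need a gradient direction), so they run at the cheaper 48.
PRETRAIN_IMAGE_SIZE = 48
SMOKE_IMAGE_SIZE = 48
N_TRAIN, N_VAL = 48, 16
N_PRETRAIN = 50
STUDY_HEADS = (1, 1, 2, 2)


def study_phantoms(seed: int, n_train=N_TRAIN, n_val=N_VAL, image_size=IMAGE_SIZE):
    cfg = PhantomConfig(image_size=image_size, seed=seed)
    return generate_dataset(n_train, cfg, "train"), generate_dataset(n_val, cfg, "val")


def learnability_run(seed: int, epochs: int = 15, level: str = "level5") -> dict:
    """Train the scaled-down network on freshly generated phantoms.

    Returns the final-epoch validation mean DSC, the per-structure DSCs and
    the full trace.
    """
    tr, va = study_phantoms(seed)
    cfg = desk_train_config(seed=seed, epochs=epochs)
    mc = tiny_config(level=level, image_size=IMAGE_SIZE, heads=STUDY_HEADS)
    result = train(tr, va, cfg, mc)
    last = result["trace"][-1]
    return {
        "final_val_mean_dsc": last["val_mean_dsc"],
        "final_per_structure": last["val_dsc_per_structure"],
        "best_val_dsc": result["best_val_dsc"],
        "trace": result["trace"],
        "result": result,
    }


def pretrain_sanity_run(seed: int, n_images: int = N_PRETRAIN, epochs: int = 10) -> dict:
    """Contrastive pretraining on unlabeled multi-site phantoms."""
    cfg = PhantomConfig(image_size=PRETRAIN_IMAGE_SIZE, seed=seed)
    images = generate_dataset(n_images, cfg, "pretrain")
    pcfg = desk_pretrain_config(seed=seed, epochs=epochs)
    enc_cfg = EncoderConfig(
        image_size=PRETRAIN_IMAGE_SIZE,
        stage_channels=(8, 16, 32, 64),
        heads=(2, 2, 2, 2),
        gat_blocks=1,
    )
    weights, result = pretrain(images, pcfg, enc_cfg)
    return {
        "loss_trace": result["loss_trace"],
        "z_std": result["z_std"],
        "weights": weights,
        "encoder_config": enc_cfg,
    }


def single_step_decreases_loss(level: str, seed: int, lr: float = 1e-3) -> bool:
    """Build a variant, take one Adam step on one batch, recheck the loss."""
    mc = tiny_config(level=level)
    cfg = PhantomConfig(image_size=SMOKE_IMAGE_SIZE, seed=seed)
    batch = generate_dataset(4, cfg, "train")
    x = onp.stack([s.image for s in batch]).astype(nn.DTYPE)[:, None]
    y = onp.stack([s.label for s in batch]).astype(onp.int64)
    params = init_model(onp.random.default_rng(seed), mc)
    bn = nn.BNState()

    def loss_fn(p):
        probs = pcgnet_forward(p, x, mc, bn, training=True)
        return deep_supervised_loss(
            probs, y, mc.num_classes, mc.deep_supervision_weights, FocalDiceConfig()
        )

    vg = value_and_grad(loss_fn)
    flat, unflatten = flatten(params)
    before, g = vg(params)
    gflat, _ = flatten(g)
    flat = Adam(weight_decay=0.0).step(flat, gflat, lr)
    after, _ = vg(unflatten(flat))
    return float(after) < float(before)
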
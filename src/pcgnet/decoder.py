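"""Progressive refinement decoder and full model assembly.

The decoder recovers resolution scale by scale.  Each prediction branch i has
a generator: two conv-BN-ReLU pairs (gamma_i) at a common feature width and a
1x1 dimension-adjust convolution (sigma_i) to class logits.  From the second
branch on, the previous branch's gamma output is bilinearly upsampled x2,
concatenated with that scale's skip (fused) features as the gamma input, and
added element-wise to the gamma output — so each scale refines the coarser
prediction instead of recomputing it:

    phi_1 = sigma_1(gamma_1(skip_4))
    phi_i = sigma_i(gamma_i([U(f_{i-1}), skip_{5-i}]) (+) U(f_{i-1})),  i=2..4

The finest logit map is upsampled x2 to the input resolution; softmax maps at
all four scales feed deep supervision during training and the argmax of the
finest map is the predicted label map.

The module also assembles the ablation variants: a CNN- or attention-only
encoder, plain skip connections vs cascade-graph fusion, and a plain one-shot
decoder vs the progressive decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as np

from . import nn
from .encoder import (
    EncoderConfig,
    conv_bn_relu,
    encode,
    init_conv_bn,
    init_encoder,
)
from .graph_fusion import CGMConfig, capped_rates, cgm_fuse, init_cgm

#: ablation variants: which encoder branches run, whether skip connections
#: pass through the cascade graph module, and which decoder is used.
LEVELS = {
    "baseline": {"branches": ("cnn",), "cgm": False, "prm": False},
    "level1": {"branches": ("cnn",), "cgm": False, "prm": True},
    "level2": {"branches": ("gat",), "cgm": False, "prm": False},
    "level3": {"branches": ("cnn", "gat"), "cgm": False, "prm": False},
    "level4": {"branches": ("cnn", "gat"), "cgm": True, "prm": False},
    "level5": {"branches": ("cnn", "gat"), "cgm": True, "prm": True},
}


@dataclass
class ModelConfig:
    image_size: int = 128
    num_classes: int = 6
    level: str = "level5"
    stage_channels: tuple = (32, 64, 128, 256)
    heads: tuple = (4, 4, 8, 8)
    gat_blocks: int = 2
    nested: bool = True
    cgm_nodes: int = 4
    cgm_rates: tuple = (1, 2, 4, 8)
    cgm_steps: int = 2
    decoder_width: int = 64
    deep_supervision_weights: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown ablation level {self.level!r}; options: {sorted(LEVELS)}")

    @property
    def variant(self) -> dict:
        return LEVELS[self.level]

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            image_size=self.image_size,
            stage_channels=self.stage_channels,
            heads=self.heads,
            gat_blocks=self.gat_blocks,
            nested=self.nested,
        )

    def cgm_config(self, stage: int) -> CGMConfig:
        res = self.image_size // (2 ** (stage + 1))
        return CGMConfig(
            n=self.cgm_nodes,
            dilation_rates=capped_rates(self.cgm_rates, res, res),
            message_steps=self.cgm_steps,
        )


def tiny_config(**overrides) -> ModelConfig:
    """Desk-scale preset used throughout the test and acceptance suites."""
    base = dict(
        image_size=48,
        stage_channels=(8, 16, 32, 64),
        heads=(2, 2, 2, 2),
        gat_blocks=1,
        cgm_nodes=2,
        cgm_rates=(1, 2),
        cgm_steps=2,
        decoder_width=16,
    )
    base.update(overrides)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def init_model(rng, cfg: ModelConfig) -> dict:
    variant = cfg.variant
    enc_cfg = cfg.encoder_config()
    ch = cfg.stage_channels
    params = {"encoder": init_encoder(rng, enc_cfg, branches=variant["branches"])}

    parallel = len(variant["branches"]) == 2
    if variant["cgm"]:
        params["skips"] = [
            init_cgm(rng, ch[s], cfg.cgm_config(s), out_channels=ch[s])
            for s in range(enc_cfg.stages)
        ]
    elif parallel:
        params["skips"] = [
            {"proj": nn.conv1x1_init(rng, ch[s], 2 * ch[s])} for s in range(enc_cfg.stages)
        ]
    else:
        params["skips"] = [{} for _ in range(enc_cfg.stages)]

    m, d = cfg.num_classes, cfg.decoder_width
    if variant["prm"]:
        dec = {"gammas": [], "sigmas": []}
        for i in range(4):
            c_skip = ch[3 - i]
            c_in = c_skip if i == 0 else c_skip + d
            dec["gammas"].append(
                {"a": init_conv_bn(rng, d, c_in), "b": init_conv_bn(rng, d, d)}
            )
            dec["sigmas"].append(nn.conv1x1_init(rng, m, d))
        params["decoder"] = dec
    else:
        dec = {"ups": []}
        for i in range(3):  # deepest feature walks up through skips 2,1,0
            c_prev = ch[3 - i]
            c_out = ch[2 - i]
            dec["ups"].append(init_conv_bn(rng, c_out, c_prev + c_out))
        dec["final"] = init_conv_bn(rng, ch[0], ch[0])
        dec["head"] = nn.conv1x1_init(rng, m, ch[0])
        params["decoder"] = dec
    return params


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def _fused_skips(params, pyramid, cfg: ModelConfig, bn, training):
    variant = cfg.variant
    fused = []
    for s, (c_feat, g_feat) in enumerate(pyramid):
        if variant["cgm"]:
            fused.append(
                cgm_fuse(
                    params["skips"][s], g_feat, c_feat, cfg.cgm_config(s), bn, f"cgm{s}", training
                )
            )
        elif c_feat is not None and g_feat is not None:
            both = np.concatenate([g_feat, c_feat], axis=1)
            pr = params["skips"][s]["proj"]
            fused.append(nn.conv1x1(both, pr["w"], pr["b"]))
        else:
            fused.append(c_feat if c_feat is not None else g_feat)
    return fused


def refine_step(params_gamma, params_sigma, low, skip, bn, key, training):
    """One progressive-refinement branch.

    ``low`` is the previous branch's gamma feature (None for the deepest
    branch); ``skip`` the fused encoder feature at this scale.  Returns the
    gamma feature and the class-logit map phi.
    """
    if low is None:
        inp = skip
    else:
        up = nn.match_spatial(nn.bilinear_upsample2x(low), skip.shape[2], skip.shape[3])
        inp = np.concatenate([up, skip], axis=1)
    feat = conv_bn_relu(params_gamma["a"], inp, bn, key + "/a", training)
    feat = conv_bn_relu(params_gamma["b"], feat, bn, key + "/b", training)
    if low is not None:
        feat = feat + up  # element-wise (+) with the upsampled previous gamma
    phi = nn.conv1x1(feat, params_sigma["w"], params_sigma["b"])
    return feat, phi


def pcgnet_forward(params, image, cfg: ModelConfig, bn=None, training=False):
    """Full forward pass; returns class-probability maps coarse -> fine.

    The progressive decoder emits four maps (input/16, /8, /4 and full
    resolution); the plain decoder emits a single full-resolution map.
    """
    pyramid = encode(params["encoder"], image, cfg.encoder_config(), bn, training)
    skips = _fused_skips(params, pyramid, cfg, bn, training)

    if cfg.variant["prm"]:
        dec = params["decoder"]
        probs = []
        feat = None
        for i in range(4):
            feat, phi = refine_step(
                dec["gammas"][i], dec["sigmas"][i], feat, skips[3 - i], bn, f"dec{i}", training
            )
            if i == 3:
                phi = nn.bilinear_upsample2x(phi)
            probs.append(nn.softmax(phi, axis=1))
        return probs

    dec = params["decoder"]
    feat = skips[3]
    for i in range(3):
        ref = skips[2 - i]
        up = nn.match_spatial(nn.bilinear_upsample2x(feat), ref.shape[2], ref.shape[3])
        feat = conv_bn_relu(
            dec["ups"][i], np.concatenate([up, ref], axis=1), bn, f"dec{i}", training
        )
    feat = nn.bilinear_upsample2x(feat)
    feat = conv_bn_relu(dec["final"], feat, bn, "dec_final", training)
    logits = nn.conv1x1(feat, dec["head"]["w"], dec["head"]["b"])
    return [nn.softmax(logits, axis=1)]


def predict_label(params, image, cfg: ModelConfig, bn=None):
    """Argmax of the finest probability map (inference mode)."""
    probs = pcgnet_forward(params, image, cfg, bn, training=False)
    import numpy as onp

    return onp.argmax(onp.asarray(probs[-1]), axis=1).astype(onp.int16)
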
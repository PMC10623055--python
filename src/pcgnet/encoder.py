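"""Parallel encoder: nested-U CNN branch + gated-axial transformer branch.

Both branches share an interface, not weights: a 3x3 (CNN) or 1x1 (GAT) stem
lifts the single-channel slice to the first stage width, then each of the
four stages transforms features at the current resolution and halves the
spatial size with a patch-merging layer, emitting matched-shape feature
pyramids (C_s, H/2^{s+1}, W/2^{s+1}) for s = 0..3.

The CNN stage is a depth-2 nested U: an internal encoder/decoder (two
patch-merge descents, bilinear ascents with skip concatenation) at constant
stage resolution, added residually to the stage input — this extracts
intra-stage multi-scale features the way nested-U salient-object encoders
do.  The GAT stage applies a configurable number of gated axial attention
blocks at the stage resolution.

Downsampling everywhere is patch merging: each 2x2 neighbourhood is folded
losslessly into channels (4C) and linearly projected, instead of discarding
pixels with pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import autograd.numpy as np

from . import nn
from .attention import AxialBlockConfig, gated_axial_block, init_axial_block

logger = logging.getLogger(__name__)

_warned_odd: set = set()  # warn once per odd size, not once per forward pass


@dataclass
class EncoderConfig:
    image_size: int = 128
    stage_channels: tuple = (32, 64, 128, 256)
    heads: tuple = (4, 4, 8, 8)
    gat_blocks: int = 2
    nested: bool = True  # depth-2 internal U in the CNN stages (off = double conv)
    input_channels: int = 1

    @property
    def stages(self) -> int:
        return len(self.stage_channels)

    def stage_resolution(self, s: int) -> int:
        """Resolution at which stage ``s`` operates (before its downsample)."""
        return self.image_size // (2**s)


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------


def init_conv_bn(rng, c_out, c_in, k=3):
    return {"conv": nn.conv_init(rng, c_out, c_in, k), "bn": nn.bn_init(c_out)}


def conv_bn_relu(params, x, bn, key, training, dilation=1):
    x = nn.conv2d(x, params["conv"]["w"], params["conv"]["b"], dilation=dilation)
    x = nn.batch_norm(x, params["bn"]["gamma"], params["bn"]["beta"], bn, key, training)
    return nn.relu(x)


def init_patch_merge(rng, c_out, c_in, identity=False):
    if identity:
        if c_out != 4 * c_in:
            raise ValueError("identity patch merge needs c_out == 4*c_in")
        import numpy as onp

        return {"proj": {"w": onp.eye(4 * c_in, dtype=nn.DTYPE), "b": onp.zeros(4 * c_in, dtype=nn.DTYPE)}}
    return {"proj": nn.conv1x1_init(rng, c_out, 4 * c_in)}


def patch_merge(params, x):
    """Fold 2x2 neighbourhoods into channels, then project linearly.

    The rearrangement is a bijection (lossless before the projection); odd
    spatial sizes are zero-padded to even with a logged warning.
    """
    h, w = x.shape[2], x.shape[3]
    if h % 2 or w % 2:
        if (h, w) not in _warned_odd:
            _warned_odd.add((h, w))
            logger.warning("patch_merge: odd spatial size %dx%d, padding to even", h, w)
        x = np.concatenate([x, np.zeros_like(x[:, :, :1, :])], axis=2) if h % 2 else x
        x = np.concatenate([x, np.zeros_like(x[:, :, :, :1])], axis=3) if w % 2 else x
    folded = nn.space_to_depth(x)
    return nn.conv1x1(folded, params["proj"]["w"], params["proj"]["b"])


# ---------------------------------------------------------------------------
# CNN branch
# ---------------------------------------------------------------------------


def init_cnn_stage(rng, c_out, c_in, nested=True):
    p = {
        "lift": init_conv_bn(rng, c_out, c_in),
        "merge": init_patch_merge(rng, c_out, c_out),
    }
    if nested:
        p.update(
            e1=init_conv_bn(rng, c_out, c_out),
            down1=init_patch_merge(rng, c_out, c_out),
            e2=init_conv_bn(rng, c_out, c_out),
            down2=init_patch_merge(rng, c_out, c_out),
            mid=init_conv_bn(rng, c_out, c_out),
            dec2=init_conv_bn(rng, c_out, 2 * c_out),
            dec1=init_conv_bn(rng, c_out, 2 * c_out),
        )
    else:
        p.update(c1=init_conv_bn(rng, c_out, c_out), c2=init_conv_bn(rng, c_out, c_out))
    return p


def cnn_stage(params, x, bn, key, training, nested=True):
    """One CNN stage: channel lift, internal (optionally nested-U) body at
    constant resolution with a residual connection, then patch-merge /2."""
    if x.shape[2] < 4 or x.shape[3] < 4:
        raise ValueError(
            f"cnn_stage needs input >= 4x4 for its internal U, got {x.shape[2]}x{x.shape[3]}"
        )
    lift = conv_bn_relu(params["lift"], x, bn, key + "/lift", training)
    if nested:
        e1 = conv_bn_relu(params["e1"], lift, bn, key + "/e1", training)
        d1 = patch_merge(params["down1"], e1)
        e2 = conv_bn_relu(params["e2"], d1, bn, key + "/e2", training)
        d2 = patch_merge(params["down2"], e2)
        mid = conv_bn_relu(params["mid"], d2, bn, key + "/mid", training)
        u2 = nn.match_spatial(nn.bilinear_upsample2x(mid), e2.shape[2], e2.shape[3])
        dec2 = conv_bn_relu(
            params["dec2"], np.concatenate([u2, e2], axis=1), bn, key + "/dec2", training
        )
        u1 = nn.match_spatial(nn.bilinear_upsample2x(dec2), e1.shape[2], e1.shape[3])
        dec1 = conv_bn_relu(
            params["dec1"], np.concatenate([u1, e1], axis=1), bn, key + "/dec1", training
        )
        body = lift + dec1
    else:
        body = conv_bn_relu(params["c1"], lift, bn, key + "/c1", training)
        body = conv_bn_relu(params["c2"], body, bn, key + "/c2", training)
    return patch_merge(params["merge"], body)


# ---------------------------------------------------------------------------
# GAT branch
# ---------------------------------------------------------------------------


def init_gat_stage(rng, c_out, c_in, span, heads, blocks):
    cfg = AxialBlockConfig(channels=c_out, heads=heads, height=span, width=span)
    return {
        "lift": {"proj": nn.conv1x1_init(rng, c_out, c_in), "bn": nn.bn_init(c_out)},
        "blocks": [init_axial_block(rng, cfg) for _ in range(blocks)],
        "merge": init_patch_merge(rng, c_out, c_out),
    }


def gat_stage(params, x, heads, bn, key, training):
    """One transformer stage: 1x1 lift, gated axial blocks, patch-merge /2."""
    x = nn.conv1x1(x, params["lift"]["proj"]["w"], params["lift"]["proj"]["b"])
    x = nn.batch_norm(
        x, params["lift"]["bn"]["gamma"], params["lift"]["bn"]["beta"], bn, key + "/lift", training
    )
    x = nn.relu(x)
    for blk in params["blocks"]:
        x = gated_axial_block(blk, x, heads)
    return patch_merge(params["merge"], x)


# ---------------------------------------------------------------------------
# full parallel encoder
# ---------------------------------------------------------------------------


def init_encoder(rng, cfg: EncoderConfig, branches=("cnn", "gat")):
    ch = cfg.stage_channels
    params = {}
    if "cnn" in branches:
        params["cnn"] = {
            "stem": nn.conv_init(rng, ch[0], cfg.input_channels, 3),
            "stages": [
                init_cnn_stage(rng, ch[s], ch[0] if s == 0 else ch[s - 1], cfg.nested)
                for s in range(cfg.stages)
            ],
        }
    if "gat" in branches:
        params["gat"] = {
            "stem": nn.conv_init(rng, ch[0], cfg.input_channels, 3),
            "stages": [
                init_gat_stage(
                    rng,
                    ch[s],
                    ch[0] if s == 0 else ch[s - 1],
                    cfg.stage_resolution(s),
                    cfg.heads[s],
                    cfg.gat_blocks,
                )
                for s in range(cfg.stages)
            ],
        }
    return params


def _check_divisible(image, stages):
    h, w = image.shape[2], image.shape[3]
    div = 2**stages
    if h % div or w % div:
        need_h = (div - h % div) % div
        need_w = (div - w % div) % div
        raise ValueError(
            f"input {h}x{w} must be divisible by {div}; pad by ({need_h}, {need_w})"
        )


def encode(params, image, cfg: EncoderConfig, bn=None, training=False):
    """Run whichever branches are present; returns a per-stage feature list.

    For the parallel encoder each entry is ``(cnn_feat, gat_feat)`` with
    identical shapes; single-branch variants return ``(feat, None)`` or
    ``(None, feat)``.
    """
    _check_divisible(image, cfg.stages)
    feats_cnn, feats_gat = None, None
    if "cnn" in params:
        x = nn.conv2d(image, params["cnn"]["stem"]["w"], params["cnn"]["stem"]["b"])
        feats_cnn = []
        for s, sp in enumerate(params["cnn"]["stages"]):
            x = cnn_stage(sp, x, bn, f"cnn/s{s}", training, nested=cfg.nested)
            feats_cnn.append(x)
    if "gat" in params:
        x = nn.conv2d(image, params["gat"]["stem"]["w"], params["gat"]["stem"]["b"])
        feats_gat = []
        for s, sp in enumerate(params["gat"]["stages"]):
            x = gat_stage(sp, x, cfg.heads[s], bn, f"gat/s{s}", training)
            feats_gat.append(x)
    out = []
    for s in range(cfg.stages):
        c = feats_cnn[s] if feats_cnn is not None else None
        g = feats_gat[s] if feats_gat is not None else None
        out.append((c, g))
    return out


def model_summary(params) -> dict:
    """Parameter counts per top-level block, plus the total."""
    counts: dict[str, int] = {}
    for path, leaf in nn.tree_leaves(params):
        top = "/".join(path.split("/")[:2])
        counts[top] = counts.get(top, 0) + leaf.size
    counts["total"] = sum(v for k, v in counts.items())
    return counts
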
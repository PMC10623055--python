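"""Cascade graph module (CGM): graph-based fusion of the two encoder branches.

At each skip level the transformer feature map X1 and the CNN feature map X2
are expanded into two node sets — n "global" nodes from X1 and n "local"
nodes from X2 — via dilated convolutions with increasing rates, so each node
sees a different receptive field.  Two edge types aggregate the sets: an
intra-set edge e1 over all ordered node pairs of one set, and an inter-set
edge e2 over all (global, local) pairs, both through the linear pair
function alpha*first + beta*second (alpha, beta learned scalars shared by
both edges) followed by a 3x3 convolution.  Messages gate each node
element-wise by sigmoid(edge), and a convolutional GRU updates node states;
after t message-passing steps every node depends on every node of both sets.
The updated nodes are concatenated and merged (3x3 conv, then 1x1 to the
output width) into the fused map that feeds the decoder skip connection.

Because the pair function is linear, the sum over all ordered pairs has the
closed form n*(alpha+beta)*sum_i(node_i) (pairs include i == j and are not
normalised by n^2 unless ``normalize_pairs`` is set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as onp

import autograd.numpy as np

from . import nn
from .encoder import conv_bn_relu, init_conv_bn


@dataclass
class CGMConfig:
    n: int = 4
    dilation_rates: tuple = (1, 2, 4, 8)
    message_steps: int = 2
    normalize_pairs: bool = False

    def __post_init__(self):
        if len(self.dilation_rates) != self.n:
            raise ValueError("need one dilation rate per node")
        if self.message_steps < 0:
            raise ValueError("message_steps must be >= 0")


def capped_rates(cfg_rates, h, w):
    """Clamp dilation rates so a 3x3 dilated kernel fits an h x w map."""
    cap = max(1, (min(h, w) - 1) // 2)
    return tuple(min(r, cap) for r in cfg_rates)


# ---------------------------------------------------------------------------
# nodes and edges
# ---------------------------------------------------------------------------


def init_cgm(rng, channels, cfg: CGMConfig, out_channels=None):
    c = channels
    ck = out_channels or channels
    return {
        "node_convs_t": [init_conv_bn(rng, c, c) for _ in range(cfg.n)],
        "node_convs_c": [init_conv_bn(rng, c, c) for _ in range(cfg.n)],
        "alpha": onp.ones((), dtype=nn.DTYPE),
        "beta": onp.ones((), dtype=nn.DTYPE),
        "e1_conv_t": nn.conv_init(rng, c, c, 3),
        "e1_conv_c": nn.conv_init(rng, c, c, 3),
        "e2_conv": nn.conv_init(rng, c, c, 3),
        "gru_t": init_conv_gru(rng, c),
        "gru_c": init_conv_gru(rng, c),
        "merge": nn.conv_init(rng, c, 2 * cfg.n * c, 3),
        "proj": nn.conv1x1_init(rng, ck, c),
    }


def build_nodes(params, x1, x2, cfg: CGMConfig, bn=None, key="cgm", training=False):
    """Dilated-convolution node sets: n global nodes from X1, n local from X2.

    Same-padded stride-1 convolutions keep every node at the input's (h, w),
    so no interpolation is needed.  A rate whose effective kernel exceeds the
    map raises, naming the rate.
    """
    h, w = x1.shape[2], x1.shape[3]
    for r in cfg.dilation_rates:
        if 2 * r + 1 > min(h, w):
            raise ValueError(
                f"dilation rate {r} needs a map of at least {2 * r + 1} pixels, got {h}x{w}"
            )
    v1 = [
        conv_bn_relu(params["node_convs_t"][i], x1, bn, f"{key}/t{i}", training, dilation=cfg.dilation_rates[i])
        for i in range(cfg.n)
    ]
    v2 = [
        conv_bn_relu(params["node_convs_c"][i], x2, bn, f"{key}/c{i}", training, dilation=cfg.dilation_rates[i])
        for i in range(cfg.n)
    ]
    return v1, v2


def pair_sum(nodes, alpha, beta, normalize=False):
    """sum over all ordered pairs (i, j) of alpha*node_i + beta*node_j."""
    n = len(nodes)
    s = nodes[0]
    for v in nodes[1:]:
        s = s + v
    out = n * (alpha * s + beta * s)
    if normalize:
        out = out / (n * n)
    return out


def pair_sum_cross(v1, v2, alpha, beta, normalize=False):
    """sum over all pairs (i, j) of alpha*t_i + beta*c_j."""
    n = len(v1)
    s1 = v1[0]
    for v in v1[1:]:
        s1 = s1 + v
    s2 = v2[0]
    for v in v2[1:]:
        s2 = s2 + v
    out = n * (alpha * s1 + beta * s2)
    if normalize:
        out = out / (n * n)
    return out


def intra_edges(params, nodes, which, alpha, beta, normalize=False):
    """Same-kind edge map e1 for one node set ('t' or 'c')."""
    conv = params[f"e1_conv_{which}"]
    return nn.conv2d(pair_sum(nodes, alpha, beta, normalize), conv["w"], conv["b"])


def inter_edges(params, v1, v2, alpha, beta, normalize=False):
    """Cross-kind edge map e2 between global and local node sets."""
    conv = params["e2_conv"]
    return nn.conv2d(pair_sum_cross(v1, v2, alpha, beta, normalize), conv["w"], conv["b"])


# ---------------------------------------------------------------------------
# convolutional GRU node update
# ---------------------------------------------------------------------------


def init_conv_gru(rng, c):
    return {
        "wz": nn.conv_init(rng, c, c, 3),
        "uz": nn.conv_init(rng, c, c, 3),
        "wr": nn.conv_init(rng, c, c, 3),
        "ur": nn.conv_init(rng, c, c, 3),
        "wh": nn.conv_init(rng, c, c, 3),
        "uh": nn.conv_init(rng, c, c, 3),
    }


def conv_gru(params, h, m):
    """Convolutional GRU: hidden = node state, input = message.

    h' = z * h + (1 - z) * tanh-candidate, so forcing the update gate z to 1
    carries the node unchanged and forcing it to 0 replaces the node with the
    candidate of its message.  The z/r/candidate convolutions on the message
    (and z/r on the hidden state) are fused into single grouped convolutions
    — same arithmetic, one dispatch instead of three.
    """
    c = h.shape[1]
    wm = np.concatenate([params["wz"]["w"], params["wr"]["w"], params["wh"]["w"]], axis=0)
    bm = np.concatenate([params["wz"]["b"], params["wr"]["b"], params["wh"]["b"]])
    mm = nn.conv2d(m, wm, bm)
    wh = np.concatenate([params["uz"]["w"], params["ur"]["w"]], axis=0)
    bh = np.concatenate([params["uz"]["b"], params["ur"]["b"]])
    hh = nn.conv2d(h, wh, bh)
    z = nn.sigmoid(mm[:, :c] + hh[:, :c])
    r = nn.sigmoid(mm[:, c : 2 * c] + hh[:, c:])
    cand = nn.tanh(mm[:, 2 * c :] + nn.conv2d(r * h, params["uh"]["w"], params["uh"]["b"]))
    return z * h + (1.0 - z) * cand


def message_step(params, nodes, e1, e2, which):
    """One message-passing update of a node set given its edge maps.

    Per-node messages: M1 = node * sigmoid(e1_own), M2 = node * sigmoid(e2);
    the GRU input is M1 + M2, its hidden state the previous node value.
    Since the GRU weights are shared within a set, all nodes run through a
    single stacked GRU call (stacking along the batch axis).
    """
    gate = nn.sigmoid(e1) + nn.sigmoid(e2)
    gru = params[f"gru_{which}"]
    n_batch = nodes[0].shape[0]
    h = np.concatenate(nodes, axis=0)
    m = h * np.concatenate([gate] * len(nodes), axis=0)
    out = conv_gru(gru, h, m)
    return [out[i * n_batch : (i + 1) * n_batch] for i in range(len(nodes))]


# ---------------------------------------------------------------------------
# full fusion
# ---------------------------------------------------------------------------


def cgm_fuse(params, x1, x2, cfg: CGMConfig, bn=None, key="cgm", training=False):
    """Build nodes, run t message-passing steps, merge into the fused map."""
    v1, v2 = build_nodes(params, x1, x2, cfg, bn, key, training)
    a, b = params["alpha"], params["beta"]
    for _ in range(cfg.message_steps):
        e1_t = intra_edges(params, v1, "t", a, b, cfg.normalize_pairs)
        e1_c = intra_edges(params, v2, "c", a, b, cfg.normalize_pairs)
        e2 = inter_edges(params, v1, v2, a, b, cfg.normalize_pairs)
        v1 = message_step(params, v1, e1_t, e2, "t")
        v2 = message_step(params, v2, e1_c, e2, "c")
    merged = np.concatenate(v1 + v2, axis=1)
    merged = nn.relu(nn.conv2d(merged, params["merge"]["w"], params["merge"]["b"]))
    return nn.conv1x1(merged, params["proj"]["w"], params["proj"]["b"])
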
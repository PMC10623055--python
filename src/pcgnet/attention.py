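"""Gated axial self-attention.

Full 2-D self-attention over an H x W feature map costs O((HW)^2).  Axial
attention factorises it into a 1-D pass along the height axis followed by a
1-D pass along the width axis, so a pixel first aggregates its column, then
its row — after both passes its receptive field is exactly its row union its
column.

Each axis pass augments the content logits q.k with two learned positional
terms and augments the values with a learned positional value table.  Four
learned scalar gates per head (G_Q, G_K, G_V1, G_V2) modulate how much the
positional terms contribute, so the layer can interpolate between purely
content-driven and strongly position-driven attention:

    logit(j -> w) = q_j.k_w / sqrt(d) + G_Q q_j.r_q[j,w] + G_K k_w.r_k[j,w]
    y_j = sum_w softmax_w(logit) * (G_V1 v_w + G_V2 r_v[j,w])

The positional tables ``r_q, r_k, r_v`` are full span x span grids of
head-dimension vectors, indexed by (query position, key position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as onp

import autograd.numpy as np

from . import nn


@dataclass
class AxialParams:
    """Hyper-parameters for one axial attention layer."""

    channels: int
    heads: int
    axis_span: int
    gate_init: float = 1.0
    bias_scale: float = 0.1

    def __post_init__(self):
        if self.channels % self.heads:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by heads ({self.heads})"
            )

    @property
    def head_dim(self) -> int:
        return self.channels // self.heads


def init_axial(rng, cfg: AxialParams) -> dict:
    """Initialise one axial attention layer.

    Gates start at ``gate_init`` (1.0 by default: positional terms fully on);
    positional tables are small random grids so they break ties but do not
    dominate the content logits at initialisation.
    """
    c, a, d, s = cfg.channels, cfg.heads, cfg.head_dim, cfg.axis_span
    g = cfg.gate_init
    return {
        "wq": nn.conv1x1_init(rng, c, c),
        "wk": nn.conv1x1_init(rng, c, c),
        "wv": nn.conv1x1_init(rng, c, c),
        "r_q": (rng.normal(0, cfg.bias_scale, (a, d, s, s))).astype(nn.DTYPE),
        "r_k": (rng.normal(0, cfg.bias_scale, (a, d, s, s))).astype(nn.DTYPE),
        "r_v": (rng.normal(0, cfg.bias_scale, (a, d, s, s))).astype(nn.DTYPE),
        "g_q": onp.full(a, g, dtype=nn.DTYPE),
        "g_k": onp.full(a, g, dtype=nn.DTYPE),
        "g_v1": onp.full(a, g, dtype=nn.DTYPE),
        "g_v2": onp.full(a, g, dtype=nn.DTYPE),
    }


def _split_heads(x, heads):
    n, c, h, w = x.shape
    return np.reshape(x, (n, heads, c // heads, h, w))


def axial_attention_width(params, x, heads, return_weights=False):
    """Width-axis gated attention; every row attends within itself only.

    ``x`` is (N, C, H, W) and W must equal the layer's axis span (the side of
    the positional tables).  Multi-head outputs are concatenated back into the
    channel axis; the caller mixes them with its 1x1 output projection.
    """
    span = params["r_q"].shape[-1]
    if x.shape[3] != span:
        raise ValueError(
            f"axis span mismatch on width axis: input W={x.shape[3]}, params span={span}"
        )
    q = _split_heads(nn.conv1x1(x, params["wq"]["w"], params["wq"]["b"]), heads)
    k = _split_heads(nn.conv1x1(x, params["wk"]["w"], params["wk"]["b"]), heads)
    v = _split_heads(nn.conv1x1(x, params["wv"]["w"], params["wv"]["b"]), heads)
    d = q.shape[2]
    scale = 1.0 / onp.sqrt(d).astype(nn.DTYPE)

    # indices: n=batch, a=head, d=head dim, i=row, j=query col, u=key col.
    # all contractions are expressed as batched matmuls (BLAS) rather than
    # einsum, which numpy evaluates on a much slower code path.
    n, a, d_, h, w = q.shape
    qt = np.transpose(q, (0, 1, 3, 4, 2))  # naijd -> query rows
    kt = np.transpose(k, (0, 1, 3, 2, 4))  # naidu
    content = np.matmul(qt, kt) * scale  # naiju

    # positional terms batch over (head, query position j)
    qp = np.reshape(np.transpose(q, (1, 4, 0, 3, 2)), (a, w, n * h, d_))  # a j (ni) d
    rq = np.transpose(params["r_q"], (0, 2, 1, 3))  # a j d u
    pos_q = np.transpose(np.reshape(np.matmul(qp, rq), (a, w, n, h, w)), (2, 0, 3, 1, 4))
    # pos_k[n,a,i,j,u] = sum_d k[n,a,d,i,u] r_k[a,d,j,u]: contract per (a, u)
    ku = np.reshape(np.transpose(k, (1, 4, 0, 3, 2)), (a, w, n * h, d_))  # a u (ni) d
    rku = np.transpose(params["r_k"], (0, 3, 1, 2))  # a u d j
    pos_k = np.transpose(np.reshape(np.matmul(ku, rku), (a, w, n, h, w)), (2, 0, 3, 4, 1))

    gq = np.reshape(params["g_q"], (1, -1, 1, 1, 1))
    gk = np.reshape(params["g_k"], (1, -1, 1, 1, 1))
    logits = content + gq * pos_q + gk * pos_k
    weights = nn.softmax(logits, axis=4)

    gv1 = np.reshape(params["g_v1"], (1, -1, 1, 1, 1))
    gv2 = np.reshape(params["g_v2"], (1, -1, 1, 1, 1))
    vt = np.transpose(v, (0, 1, 3, 4, 2))  # naiud
    out = np.matmul(weights * gv1, vt)  # naijd
    # positional values: sum_u A[n,a,i,j,u] r_v[a,d,j,u], batch over (a, j)
    wp = np.reshape(np.transpose(weights * gv2, (1, 3, 0, 2, 4)), (a, w, n * h, w))  # a j (ni) u
    rv = np.transpose(params["r_v"], (0, 2, 3, 1))  # a j u d
    out = out + np.transpose(np.reshape(np.matmul(wp, rv), (a, w, n, h, d_)), (2, 0, 3, 1, 4))
    out = np.reshape(np.transpose(out, (0, 1, 4, 2, 3)), (n, a * d_, h, w))
    if return_weights:
        return out, weights
    return out


def axial_attention_height(params, x, heads, return_weights=False):
    """Height-axis analogue: transpose, run the width op, transpose back."""
    span = params["r_q"].shape[-1]
    if x.shape[2] != span:
        raise ValueError(
            f"axis span mismatch on height axis: input H={x.shape[2]}, params span={span}"
        )
    xt = np.transpose(x, (0, 1, 3, 2))
    res = axial_attention_width(params, xt, heads, return_weights=return_weights)
    if return_weights:
        out, w = res
        return np.transpose(out, (0, 1, 3, 2)), w
    return np.transpose(res, (0, 1, 3, 2))


@dataclass
class AxialBlockConfig:
    channels: int
    heads: int
    height: int
    width: int
    gate_init: float = 1.0
    zero_init_out: bool = False
    attn: AxialParams = field(init=False)

    def __post_init__(self):
        # span differs per sub-layer; store a template, spans fixed below
        self.attn = AxialParams(self.channels, self.heads, self.height, self.gate_init)


def init_axial_block(rng, cfg: AxialBlockConfig) -> dict:
    c = cfg.channels
    return {
        "h": {
            "pin": nn.conv1x1_init(rng, c, c),
            "attn": init_axial(rng, AxialParams(c, cfg.heads, cfg.height, cfg.gate_init)),
            "pout": nn.conv1x1_init(rng, c, c, zero=cfg.zero_init_out),
        },
        "w": {
            "pin": nn.conv1x1_init(rng, c, c),
            "attn": init_axial(rng, AxialParams(c, cfg.heads, cfg.width, cfg.gate_init)),
            "pout": nn.conv1x1_init(rng, c, c, zero=cfg.zero_init_out),
        },
    }


def gated_axial_block(params, x, heads):
    """Height-axis and width-axis attention as residual sub-layers.

    Both sub-layers read the block *input*: the output is
    ``x + P_out_h(attend_h(P_in_h(x))) + P_out_w(attend_w(P_in_w(x)))``.
    This keeps the single-block dependency set of pixel (i, j) exactly
    row i union column j — feeding the width pass the height-attended
    features instead would make every pixel depend on the whole image
    through two hops, which is *not* the advertised axial locality.  Global
    context still accumulates across stacked blocks.  A zero-initialised
    output projection makes the block the identity.
    """
    ph, pw = params["h"], params["w"]
    inner_h = nn.conv1x1(x, ph["pin"]["w"], ph["pin"]["b"])
    inner_h = axial_attention_height(ph["attn"], inner_h, heads)
    inner_w = nn.conv1x1(x, pw["pin"]["w"], pw["pin"]["b"])
    inner_w = axial_attention_width(pw["attn"], inner_w, heads)
    return (
        x
        + nn.conv1x1(inner_h, ph["pout"]["w"], ph["pout"]["b"])
        + nn.conv1x1(inner_w, pw["pout"]["w"], pw["pout"]["b"])
    )
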
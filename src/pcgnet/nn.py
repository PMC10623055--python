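"""Minimal neural-network substrate on numpy reverse-mode autodiff.

Everything in this package runs on CPU through :mod:`autograd`.  Parameters
are plain nested dicts of ``float32`` numpy arrays; layers are pure functions
``f(params, x, ...) -> array`` so the whole model is differentiable with
``autograd.grad`` over the parameter tree.

The 2-D convolution is registered as a custom autograd primitive with
hand-written vector-Jacobian products.  Both the forward pass and the two
backward passes are expressed as K*K shift-and-matmul steps, which avoids
materialising im2col patch tensors and is roughly an order of magnitude
faster than tracing the gather-based formulation.
"""

from __future__ import annotations

import numpy as onp

import autograd.numpy as np
from autograd.extend import defvjp, primitive
from autograd.tracer import getval

DTYPE = onp.float32

# ---------------------------------------------------------------------------
# stop-gradient
# ---------------------------------------------------------------------------

stop_gradient = primitive(lambda x: x)
defvjp(stop_gradient, None)
stop_gradient.__doc__ = "Identity in the forward pass; blocks all gradient flow."


# ---------------------------------------------------------------------------
# convolution primitive (stride 1, 'same' padding, optional dilation)
# ---------------------------------------------------------------------------


def _pad_hw(x, r):
    if r == 0:
        return x
    n, c, h, w = x.shape
    out = onp.zeros((n, c, h + 2 * r, w + 2 * r), dtype=x.dtype)
    out[:, :, r : r + h, r : r + w] = x
    return out


@primitive
def conv2d_raw(x, w, dilation=1):
    """Correlate ``x`` (N,C,H,W) with ``w`` (Co,C,K,K); stride 1, same padding."""
    n, c, h, wd = x.shape
    co, ci, k, _ = w.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {ci}")
    r = (k // 2) * dilation
    xp = _pad_hw(x, r)
    out = onp.zeros((n, co, h, wd), dtype=x.dtype)
    for kh in range(k):
        for kw in range(k):
            xs = xp[:, :, kh * dilation : kh * dilation + h, kw * dilation : kw * dilation + wd]
            out += onp.matmul(w[:, :, kh, kw], xs.reshape(n, c, -1)).reshape(n, co, h, wd)
    return out


def _conv2d_vjp_x(ans, x, w, dilation=1):
    n, c, h, wd = x.shape
    co, _, k, _ = w.shape
    r = (k // 2) * dilation

    def vjp(g):
        gp = _pad_hw(g, r)
        gx = onp.zeros_like(x)
        for kh in range(k):
            for kw in range(k):
                sh, sw = 2 * r - kh * dilation, 2 * r - kw * dilation
                gs = gp[:, :, sh : sh + h, sw : sw + wd]
                gx += onp.matmul(w[:, :, kh, kw].T, gs.reshape(n, co, -1)).reshape(n, c, h, wd)
        return gx

    return vjp


def _conv2d_vjp_w(ans, x, w, dilation=1):
    n, c, h, wd = x.shape
    co, _, k, _ = w.shape
    r = (k // 2) * dilation

    def vjp(g):
        xp = _pad_hw(x, r)
        gw = onp.zeros_like(w)
        g2 = onp.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(co, -1)
        for kh in range(k):
            for kw in range(k):
                xs = xp[:, :, kh * dilation : kh * dilation + h, kw * dilation : kw * dilation + wd]
                xs = onp.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(c, -1)
                gw[:, :, kh, kw] = g2 @ xs.T
        return gw

    return vjp


defvjp(conv2d_raw, _conv2d_vjp_x, _conv2d_vjp_w)


def conv2d(x, w, b=None, dilation=1):
    """Same-padded stride-1 convolution with optional bias (Co,)."""
    out = conv2d_raw(x, w, dilation)
    if b is not None:
        out = out + np.reshape(b, (1, -1, 1, 1))
    return out


def conv1x1(x, w, b=None):
    """Pointwise channel mixing; ``w`` has shape (Co, C)."""
    n, c, h, wd = x.shape
    out = np.reshape(np.matmul(w, np.reshape(x, (n, c, h * wd))), (n, -1, h, wd))
    if b is not None:
        out = out + np.reshape(b, (1, -1, 1, 1))
    return out


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    # clamp where tanh is saturated anyway; avoids cosh overflow in the vjp
    return 0.5 * (np.tanh(np.clip(0.5 * x, -30.0, 30.0)) + 1.0)


def tanh(x):
    return np.tanh(np.clip(x, -30.0, 30.0))


def softmax(x, axis=1):
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=1):
    m = np.max(x, axis=axis, keepdims=True)
    s = x - m
    return s - np.log(np.sum(np.exp(s), axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


class BNState:
    """Mutable running-statistics store for all batch-norm layers of a model.

    Running statistics are updated *outside* the autodiff trace (via
    ``getval``), so the update is a benign side effect: normalisation during
    training uses in-trace batch statistics, inference uses the stored
    running mean/variance.
    """

    def __init__(self, momentum: float = 0.9):
        self.momentum = momentum
        self.stats: dict[str, tuple[onp.ndarray, onp.ndarray]] = {}

    def update(self, key, mean, var):
        m = self.momentum
        if key in self.stats:
            rm, rv = self.stats[key]
            self.stats[key] = (m * rm + (1 - m) * mean, m * rv + (1 - m) * var)
        else:
            self.stats[key] = (mean, var)

    def get(self, key, channels):
        if key in self.stats:
            return self.stats[key]
        return (onp.zeros(channels, dtype=DTYPE), onp.ones(channels, dtype=DTYPE))

    def copy(self):
        out = BNState(self.momentum)
        out.stats = {k: (m.copy(), v.copy()) for k, (m, v) in self.stats.items()}
        return out


def batch_norm(x, gamma, beta, bn: BNState | None, key: str, training: bool, eps=1e-5):
    """Channel-wise batch normalisation over (N, H, W) for NCHW input."""
    if training or bn is None or key not in bn.stats:
        mu = np.mean(x, axis=(0, 2, 3))
        var = np.var(x, axis=(0, 2, 3))
        if bn is not None and training:
            bn.update(key, getval(mu).astype(DTYPE), getval(var).astype(DTYPE))
    else:
        mu, var = bn.get(key, x.shape[1])
    xhat = (x - np.reshape(mu, (1, -1, 1, 1))) / np.sqrt(np.reshape(var, (1, -1, 1, 1)) + eps)
    return xhat * np.reshape(gamma, (1, -1, 1, 1)) + np.reshape(beta, (1, -1, 1, 1))


def batch_norm_vec(x, gamma, beta, bn: BNState | None, key: str, training: bool, eps=1e-5):
    """Batch normalisation for (N, D) vectors (projector/predictor MLPs)."""
    if training or bn is None or key not in bn.stats:
        mu = np.mean(x, axis=0)
        var = np.var(x, axis=0)
        if bn is not None and training:
            bn.update(key, getval(mu).astype(DTYPE), getval(var).astype(DTYPE))
    else:
        mu, var = bn.get(key, x.shape[1])
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _upsample2x_index(n):
    i = (onp.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = onp.clip(onp.floor(i).astype(int), 0, n - 1)
    i1 = onp.clip(i0 + 1, 0, n - 1)
    t = (i - onp.floor(i)).astype(DTYPE)
    # where both neighbours clamp to the same pixel the weight is irrelevant
    return i0, i1, t


def bilinear_upsample2x(x):
    """Bilinear x2 upsampling (half-pixel centres, edges replicated)."""
    h, w = x.shape[2], x.shape[3]
    i0, i1, ti = _upsample2x_index(h)
    j0, j1, tj = _upsample2x_index(w)
    rows = x[:, :, i0, :] * (1 - ti)[None, None, :, None] + x[:, :, i1, :] * ti[None, None, :, None]
    out = rows[:, :, :, j0] * (1 - tj)[None, None, None, :] + rows[:, :, :, j1] * tj[None, None, None, :]
    return out


def space_to_depth(x):
    """Fold each 2x2 neighbourhood into channels: (N,C,H,W) -> (N,4C,H/2,W/2)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"space_to_depth needs even spatial size, got {h}x{w}")
    x = np.reshape(x, (n, c, h // 2, 2, w // 2, 2))
    x = np.transpose(x, (0, 1, 3, 5, 2, 4))
    return np.reshape(x, (n, 4 * c, h // 2, w // 2))


def depth_to_space(x):
    """Inverse of :func:`space_to_depth`."""
    n, c4, h, w = x.shape
    c = c4 // 4
    x = np.reshape(x, (n, c, 2, 2, h, w))
    x = np.transpose(x, (0, 1, 4, 2, 5, 3))
    return np.reshape(x, (n, c, 2 * h, 2 * w))


def match_spatial(x, h, w):
    """Crop (top-left) or zero-pad (bottom/right) to an exact (h, w)."""
    xh, xw = x.shape[2], x.shape[3]
    if xh > h:
        x = x[:, :, :h, :]
    if xw > w:
        x = x[:, :, :, :w]
    if x.shape[2] < h:
        pad = np.zeros((x.shape[0], x.shape[1], h - x.shape[2], x.shape[3]), dtype=x.dtype)
        x = np.concatenate([x, pad], axis=2)
    if x.shape[3] < w:
        pad = np.zeros((x.shape[0], x.shape[1], x.shape[2], w - x.shape[3]), dtype=x.dtype)
        x = np.concatenate([x, pad], axis=3)
    return x


def global_avg_pool(x):
    return np.mean(x, axis=(2, 3))


def linear(x, w, b=None):
    out = np.dot(x, w.T)
    if b is not None:
        out = out + b
    return out


# ---------------------------------------------------------------------------
# initialisation and parameter-tree helpers
# ---------------------------------------------------------------------------


def conv_init(rng, c_out, c_in, k):
    fan_in = c_in * k * k
    w = rng.normal(0.0, onp.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
    return {"w": w.astype(DTYPE), "b": onp.zeros(c_out, dtype=DTYPE)}


def conv1x1_init(rng, c_out, c_in, zero=False):
    if zero:
        w = onp.zeros((c_out, c_in))
    else:
        w = rng.normal(0.0, onp.sqrt(2.0 / c_in), size=(c_out, c_in))
    return {"w": w.astype(DTYPE), "b": onp.zeros(c_out, dtype=DTYPE)}


def linear_init(rng, d_out, d_in):
    w = rng.normal(0.0, onp.sqrt(2.0 / d_in), size=(d_out, d_in))
    return {"w": w.astype(DTYPE), "b": onp.zeros(d_out, dtype=DTYPE)}


def bn_init(channels):
    return {"gamma": onp.ones(channels, dtype=DTYPE), "beta": onp.zeros(channels, dtype=DTYPE)}


def tree_map(f, tree):
    if isinstance(tree, dict):
        return {k: tree_map(f, v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_map(f, v) for v in tree)
    return f(tree)


def tree_leaves(tree, prefix=""):
    """Yield (path, array) pairs in deterministic (sorted) order."""
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k], f"{prefix}{k}/")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from tree_leaves(v, f"{prefix}{i}/")
    else:
        yield prefix[:-1], tree


def count_params(tree):
    return int(sum(leaf.size for _, leaf in tree_leaves(tree)))
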
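"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as explicit loops over positions and
set elements, sharing no code path with the vectorised implementations it
checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def _softmax(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def axial_width_bruteforce(params, x, heads):
    """Triple-loop evaluation of gated axial attention along the width axis.

    For every (row i, query column j) the attention logits over key columns u
    are q.k/sqrt(d) + G_Q q.r_q[j,u] + G_K k.r_k[j,u]; the output is the
    softmax-weighted sum of G_V1 v_u + G_V2 r_v[j,u].
    """
    n, c, h, w = x.shape
    d = c // heads

    def proj(p):
        out = np.zeros((n, c, h, w))
        for o in range(c):
            for ci in range(c):
                out[:, o] += p["w"][o, ci] * x[:, ci]
            out[:, o] += p["b"][o]
        return out.reshape(n, heads, d, h, w)

    q, k, v = proj(params["wq"]), proj(params["wk"]), proj(params["wv"])
    rq, rk, rv = params["r_q"], params["r_k"], params["r_v"]
    gq, gk, gv1, gv2 = params["g_q"], params["g_k"], params["g_v1"], params["g_v2"]
    y = np.zeros((n, heads, d, h, w))
    for b in range(n):
        for a in range(heads):
            for i in range(h):
                for j in range(w):
                    logits = np.zeros(w)
                    for u in range(w):
                        logits[u] = (
                            float(q[b, a, :, i, j] @ k[b, a, :, i, u]) / np.sqrt(d)
                            + gq[a] * float(q[b, a, :, i, j] @ rq[a, :, j, u])
                            + gk[a] * float(k[b, a, :, i, u] @ rk[a, :, j, u])
                        )
                    wts = _softmax(logits)
                    acc = np.zeros(d)
                    for u in range(w):
                        acc += wts[u] * (gv1[a] * v[b, a, :, i, u] + gv2[a] * rv[a, :, j, u])
                    y[b, a, :, i, j] = acc
    return y.reshape(n, c, h, w)


# ---------------------------------------------------------------------------
# surface-distance oracles
# ---------------------------------------------------------------------------


def boundary_points(mask):
    """Boundary = mask pixels with a 4-neighbour outside the mask (or image)."""
    hh, ww = mask.shape
    pts = []
    for i in range(hh):
        for j in range(ww):
            if not mask[i, j]:
                continue
            for a, b in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
                if not (0 <= a < hh and 0 <= b < ww) or not mask[a, b]:
                    pts.append((i, j))
                    break
    return np.asarray(pts, dtype=float)


def hausdorff_bruteforce(pred, true, spacing=1.0):
    b1 = boundary_points(np.asarray(pred, bool)) * spacing
    b2 = boundary_points(np.asarray(true, bool)) * spacing
    dmat = cdist(b1, b2)
    return max(dmat.min(axis=1).max(), dmat.min(axis=0).max())


def assd_bruteforce(pred, true, spacing=1.0):
    b1 = boundary_points(np.asarray(pred, bool)) * spacing
    b2 = boundary_points(np.asarray(true, bool)) * spacing
    dmat = cdist(b1, b2)
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return pooled.mean()
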
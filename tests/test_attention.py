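"""Gated axial attention: oracle equivalence, symmetry, locality, gradients."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from oracles import axial_width_bruteforce
from pcgnet import nn
from pcgnet.attention import (
    AxialBlockConfig,
    AxialParams,
    axial_attention_height,
    axial_attention_width,
    gated_axial_block,
    init_axial,
    init_axial_block,
)


class TestWidthAttention:
    @pytest.mark.parametrize("h,w,c,heads", [(3, 3, 2, 1), (5, 4, 4, 2), (2, 7, 6, 2)])
    def test_matches_bruteforce(self, rng, h, w, c, heads):
        params = init_axial(rng, AxialParams(c, heads, w))
        x = rng.normal(size=(2, c, h, w)).astype(np.float32)
        ref = axial_width_bruteforce(params, x, heads)
        got = axial_attention_width(params, x, heads)
        assert np.abs(ref - got).max() < 1e-5

    def test_single_key_is_value_projection(self, rng):
        """W=1: softmax over one key is 1, so output = value projection."""
        params = init_axial(rng, AxialParams(4, 1, 1))
        for k in ("r_q", "r_k", "r_v"):
            params[k] = np.zeros_like(params[k])
        x = rng.normal(size=(1, 4, 5, 1)).astype(np.float32)
        out = axial_attention_width(params, x, 1)
        v = nn.conv1x1(x, params["wv"]["w"], params["wv"]["b"])
        assert np.allclose(out, v, atol=1e-6)

    def test_constant_logits_average_values(self, rng):
        """Zero keys and gates: uniform weights, each row outputs its mean value."""
        params = init_axial(rng, AxialParams(4, 1, 6))
        params["wk"]["w"] = np.zeros_like(params["wk"]["w"])
        params["g_q"][:] = 0.0
        params["g_k"][:] = 0.0
        for k in ("r_q", "r_k", "r_v"):
            params[k] = np.zeros_like(params[k])
        x = rng.normal(size=(1, 4, 3, 6)).astype(np.float32)
        out = axial_attention_width(params, x, 1)
        v = nn.conv1x1(x, params["wv"]["w"], params["wv"]["b"])
        assert np.allclose(out, np.mean(v, axis=3, keepdims=True) * np.ones_like(v), atol=1e-5)

    def test_rows_do_not_mix(self, rng):
        params = init_axial(rng, AxialParams(2, 1, 5))
        x = rng.normal(size=(1, 2, 4, 5)).astype(np.float32)
        base = axial_attention_width(params, x, 1)
        x2 = x.copy()
        x2[0, :, 2, :] += 1.0  # perturb one row
        out = axial_attention_width(params, x2, 1)
        changed = np.abs(out - base).max(axis=(0, 1, 3)) > 1e-7
        assert changed[2] and not changed[[0, 1, 3]].any()

    def test_span_mismatch_names_axis(self, rng):
        params = init_axial(rng, AxialParams(2, 1, 5))
        with pytest.raises(ValueError, match="width"):
            axial_attention_width(params, np.zeros((1, 2, 4, 4), np.float32), 1)
        with pytest.raises(ValueError, match="height"):
            axial_attention_height(params, np.zeros((1, 2, 4, 5), np.float32), 1)


class TestHeightAttention:
    def test_equals_transposed_width(self, rng):
        params = init_axial(rng, AxialParams(4, 2, 4))
        x = rng.normal(size=(2, 4, 4, 6)).astype(np.float32)
        got = axial_attention_height(params, x, 2)
        ref = np.transpose(
            axial_attention_width(params, np.transpose(x, (0, 1, 3, 2)), 2), (0, 1, 3, 2)
        )
        assert np.allclose(got, ref)

    def test_matches_bruteforce_transposed(self, rng):
        params = init_axial(rng, AxialParams(4, 1, 4))
        x = rng.normal(size=(1, 4, 4, 3)).astype(np.float32)
        ref = axial_width_bruteforce(params, np.transpose(x, (0, 1, 3, 2)), 1)
        got = axial_attention_height(params, x, 1)
        assert np.abs(np.transpose(ref, (0, 1, 3, 2)) - got).max() < 1e-5


class TestAxialBlock:
    def test_zero_output_projection_is_identity(self, rng):
        cfg = AxialBlockConfig(channels=4, heads=2, height=6, width=6, zero_init_out=True)
        params = init_axial_block(rng, cfg)
        x = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)
        assert np.allclose(gated_axial_block(params, x, 2), x)

    def test_attention_weights_normalised(self, rng):
        params = init_axial(rng, AxialParams(4, 2, 5))
        x = rng.normal(size=(2, 4, 3, 5)).astype(np.float32)
        _, weights = axial_attention_width(params, x, 2, return_weights=True)
        assert np.abs(np.asarray(weights).sum(axis=4) - 1.0).max() < 1e-6

    def test_receptive_field_is_row_union_column(self, rng):
        """A single block lets pixel (i,j) see exactly row i and column j."""
        cfg = AxialBlockConfig(channels=2, heads=1, height=5, width=5)
        params = init_axial_block(rng, cfg)
        x = rng.normal(size=(1, 2, 5, 5)).astype(np.float64)
        base = gated_axial_block(params, x, 1)
        i, j = 1, 3
        for ip in range(5):
            for jp in range(5):
                xp = x.copy()
                xp[0, :, ip, jp] += 0.5
                delta = np.abs(gated_axial_block(params, xp, 1)[0, :, i, j] - base[0, :, i, j]).max()
                if ip == i or jp == j:
                    assert delta > 1e-9, (ip, jp)
                else:
                    assert delta < 1e-12, (ip, jp)

    def test_all_parameter_groups_receive_gradient(self, rng):
        """Projections, positional tables and gates all train on a regression task."""
        cfg = AxialBlockConfig(channels=4, heads=2, height=4, width=4)
        params = init_axial_block(rng, cfg)
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float64)
        target = rng.normal(size=(2, 4, 4, 4))

        def loss(p):
            return anp.sum((gated_axial_block(p, x, 2) - target) ** 2)

        g = grad(loss)(params)
        for sub in ("h", "w"):
            for name in ("wq", "wk", "wv"):
                assert np.abs(g[sub]["attn"][name]["w"]).max() > 0
            for name in ("r_q", "r_k", "r_v", "g_q", "g_k", "g_v1", "g_v2"):
                assert np.abs(g[sub]["attn"][name]).max() > 0
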
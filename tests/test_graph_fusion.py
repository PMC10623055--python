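"""Cascade graph module: nodes, edges, GRU updates, fusion contracts."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from pcgnet import nn
from pcgnet.graph_fusion import (
    CGMConfig,
    build_nodes,
    capped_rates,
    cgm_fuse,
    conv_gru,
    init_cgm,
    init_conv_gru,
    inter_edges,
    intra_edges,
    message_step,
    pair_sum,
    pair_sum_cross,
)

CFG2 = CGMConfig(n=2, dilation_rates=(1, 2), message_steps=2)


def _delta_kernel(c):
    w = np.zeros((c, c, 3, 3), np.float32)
    for i in range(c):
        w[i, i, 1, 1] = 1.0
    return w


class TestBuildNodes:
    def test_shapes(self, rng):
        params = init_cgm(rng, 4, CFG2)
        x1 = rng.random((2, 4, 8, 8)).astype(np.float32)
        x2 = rng.random((2, 4, 8, 8)).astype(np.float32)
        v1, v2 = build_nodes(params, x1, x2, CFG2)
        assert len(v1) == len(v2) == 2
        for v in v1 + v2:
            assert v.shape == (2, 4, 8, 8)

    def test_identity_conv_passes_input_through(self, rng):
        cfg = CGMConfig(n=1, dilation_rates=(1,), message_steps=1)
        params = init_cgm(rng, 3, cfg)
        params["node_convs_t"][0]["conv"]["w"] = _delta_kernel(3)
        params["node_convs_t"][0]["conv"]["b"][:] = 0
        x = rng.random((1, 3, 6, 6)).astype(np.float32) + 0.5  # positive, relu-transparent
        bn = nn.BNState()
        bn.stats["k/t0"] = (np.zeros(3, np.float32), np.ones(3, np.float32))
        v1, _ = build_nodes(params, x, x, cfg, bn=bn, key="k", training=False)
        assert np.allclose(v1[0], x, atol=2e-5)

    def test_oversized_dilation_names_rate(self, rng):
        cfg = CGMConfig(n=2, dilation_rates=(1, 4), message_steps=1)
        params = init_cgm(rng, 2, cfg)
        x = np.zeros((1, 2, 6, 6), np.float32)
        with pytest.raises(ValueError, match="rate 4"):
            build_nodes(params, x, x, cfg)

    def test_dilated_node_has_wider_footprint(self, rng):
        """A rate-2 node reacts to a pixel 2 steps away; a rate-1 node does not."""
        params = init_cgm(rng, 2, CFG2)
        bn = nn.BNState()  # frozen identity stats: keep the probe purely convolutional
        for i in range(2):
            for kind in "tc":
                bn.stats[f"k/{kind}{i}"] = (np.zeros(2, np.float32), np.ones(2, np.float32))
        delta = np.zeros((1, 2, 9, 9), np.float32)
        base_v1, _ = build_nodes(params, delta, delta, CFG2, bn=bn, key="k", training=False)
        bumped = delta.copy()
        bumped[0, :, 4, 6] = 1.0  # two columns from the probe point (4,4)
        v1, _ = build_nodes(params, bumped, delta, CFG2, bn=bn, key="k", training=False)
        change_r1 = np.abs(v1[0] - base_v1[0])[0, :, 4, 4].max()
        change_r2 = np.abs(v1[1] - base_v1[1])[0, :, 4, 4].max()
        assert change_r2 > 1e-7 and change_r1 < 1e-7

    def test_capped_rates(self):
        assert capped_rates((1, 2, 4, 8), 8, 8) == (1, 2, 3, 3)
        assert capped_rates((1, 2), 48, 48) == (1, 2)


class TestEdges:
    def test_pair_sum_closed_form_alpha_only(self, rng):
        """alpha=1, beta=0: each node appears n times as the first element."""
        nodes = [rng.random((1, 2, 4, 4)) for _ in range(3)]
        got = pair_sum(nodes, 1.0, 0.0)
        assert np.allclose(got, 3 * sum(nodes))

    def test_pair_sum_matches_explicit_double_loop(self, rng):
        nodes = [rng.random((1, 2, 3, 3)) for _ in range(3)]
        a, b = 0.7, -0.3
        ref = sum(a * nodes[i] + b * nodes[j] for i in range(3) for j in range(3))
        assert np.allclose(pair_sum(nodes, a, b), ref, atol=1e-6)
        v2 = [rng.random((1, 2, 3, 3)) for _ in range(3)]
        ref2 = sum(a * nodes[i] + b * v2[j] for i in range(3) for j in range(3))
        assert np.allclose(pair_sum_cross(nodes, v2, a, b), ref2, atol=1e-6)

    def test_zero_nodes_give_conv_bias(self, rng):
        params = init_cgm(rng, 2, CFG2)
        zeros = [np.zeros((1, 2, 5, 5), np.float32)] * 2
        e1 = intra_edges(params, zeros, "t", 1.0, 1.0)
        assert np.allclose(np.asarray(e1)[0, :, 2, 2], params["e1_conv_t"]["b"], atol=1e-6)

    def test_inter_equals_intra_with_tied_weights_and_same_sets(self, rng):
        params = init_cgm(rng, 2, CFG2)
        params["e2_conv"] = params["e1_conv_t"]
        v = [rng.random((1, 2, 5, 5)).astype(np.float32) for _ in range(2)]
        assert np.allclose(
            inter_edges(params, v, v, 0.5, 0.5), intra_edges(params, v, "t", 0.5, 0.5), atol=1e-6
        )

    def test_beta_zero_makes_e2_independent_of_v2(self, rng):
        params = init_cgm(rng, 2, CFG2)
        v1 = [rng.random((1, 2, 5, 5)).astype(np.float32) for _ in range(2)]
        v2a = [rng.random((1, 2, 5, 5)).astype(np.float32) for _ in range(2)]
        v2b = [rng.random((1, 2, 5, 5)).astype(np.float32) for _ in range(2)]
        assert np.allclose(
            inter_edges(params, v1, v2a, 1.0, 0.0), inter_edges(params, v1, v2b, 1.0, 0.0)
        )


class TestConvGRU:
    def _forced_gate_params(self, rng, c, z_bias):
        params = init_conv_gru(rng, c)
        params["wz"]["w"] = np.zeros_like(params["wz"]["w"])
        params["uz"]["w"] = np.zeros_like(params["uz"]["w"])
        params["wz"]["b"] = np.full(c, z_bias, np.float32)
        return params

    def test_update_gate_one_carries_hidden(self, rng):
        params = self._forced_gate_params(rng, 2, 50.0)  # sigmoid -> 1
        h = rng.random((1, 2, 4, 4)).astype(np.float32)
        m = rng.random((1, 2, 4, 4)).astype(np.float32)
        assert np.allclose(conv_gru(params, h, m), h, atol=1e-6)

    def test_update_gate_zero_gives_candidate_scalar_case(self, rng):
        """1x1x1 node with unit kernels: h' = tanh(m + r*h), r = sigmoid(m + h)."""
        params = self._forced_gate_params(rng, 1, -50.0)  # z -> 0
        for k in ("wr", "ur", "wh", "uh"):
            params[k]["w"] = np.ones((1, 1, 3, 3), np.float32) * 0.0
            params[k]["w"][0, 0, 1, 1] = 1.0
            params[k]["b"][:] = 0.0
        h = np.full((1, 1, 1, 1), 0.3, np.float32)
        m = np.full((1, 1, 1, 1), -0.7, np.float32)
        r = 1 / (1 + np.exp(0.7 - 0.3))
        expected = np.tanh(-0.7 + r * 0.3)
        assert conv_gru(params, h, m)[0, 0, 0, 0] == pytest.approx(expected, abs=1e-6)

    def test_message_step_preserves_shapes(self, rng):
        params = init_cgm(rng, 3, CFG2)
        nodes = [rng.random((2, 3, 5, 5)).astype(np.float32) for _ in range(2)]
        e = rng.random((2, 3, 5, 5)).astype(np.float32)
        out = message_step(params, nodes, e, e, "t")
        assert len(out) == 2 and all(o.shape == (2, 3, 5, 5) for o in out)


class TestCgmFuse:
    def test_output_shape_and_gradients_reach_both_inputs(self, rng):
        params = init_cgm(rng, 4, CFG2, out_channels=6)
        x1 = rng.random((1, 4, 8, 8)).astype(np.float64)
        x2 = rng.random((1, 4, 8, 8)).astype(np.float64)
        out = cgm_fuse(params, x1, x2, CFG2)
        assert out.shape == (1, 6, 8, 8)
        g1 = grad(lambda a: anp.sum(cgm_fuse(params, a, x2, CFG2) ** 2))(x1)
        g2 = grad(lambda a: anp.sum(cgm_fuse(params, x1, a, CFG2) ** 2))(x2)
        assert np.abs(g1).max() > 0 and np.abs(g2).max() > 0

    def test_message_passing_changes_output(self, rng):
        params = init_cgm(rng, 2, CFG2)
        x1 = rng.random((1, 2, 6, 6)).astype(np.float32)
        x2 = rng.random((1, 2, 6, 6)).astype(np.float32)
        out_t2 = cgm_fuse(params, x1, x2, CFG2)
        cfg0 = CGMConfig(n=2, dilation_rates=(1, 2), message_steps=0)
        out_t0 = cgm_fuse(params, x1, x2, cfg0)
        assert np.abs(np.asarray(out_t2) - np.asarray(out_t0)).max() > 1e-6

    def test_bounded_inputs_stay_finite(self, rng):
        params = init_cgm(rng, 2, CFG2)
        x = np.full((1, 2, 6, 6), 1e3, np.float32)
        out = cgm_fuse(params, x, -x, CFG2)
        assert np.isfinite(np.asarray(out)).all()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="rate"):
            CGMConfig(n=2, dilation_rates=(1, 2, 4))
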
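"""Autograd engine correctness and network-block contracts."""

import numpy as np
import pytest

from leafdet.nn import (
    C3,
    CAM,
    EPSA,
    Conv2d,
    Focus,
    GhostBlock,
    ImprovedCSP,
    InvertedResidual,
    SPP,
    Sequential,
    Tensor,
    count_parameters,
    manual_seed,
)
from leafdet.nn.autograd import (
    batch_norm2d,
    bce_with_logits,
    conv2d,
    max_pool2d,
    softmax,
    space_to_depth2,
    upsample_nearest2x,
)
from leafdet.nn.layers import Module


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


def assert_grad_matches(make_loss, *tensors, tol=2e-2):
    for t in tensors:
        t.grad = None
    make_loss().backward()
    for t in tensors:
        ng = numeric_grad(lambda: float(make_loss().data), t.data)
        scale = np.abs(ng).max() + 1e-6
        assert np.abs(t.grad - ng).max() / scale < tol


class TestAutogradGradients:
    """Every structured op is checked against finite differences."""

    def setup_method(self):
        rng = np.random.default_rng(3)
        self.x = Tensor(rng.standard_normal((2, 4, 6, 6)), requires_grad=True)
        self.mult = Tensor(rng.standard_normal((2, 4, 6, 6)))
        self.rng = rng

    def test_conv_strided(self):
        w = Tensor(self.rng.standard_normal((6, 4, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(self.rng.standard_normal(6) * 0.1, requires_grad=True)
        assert_grad_matches(
            lambda: conv2d(self.x, w, b, stride=2, padding=1).sum(), self.x, w, b
        )

    def test_conv_1x1_fast_path(self):
        w = Tensor(self.rng.standard_normal((8, 4, 1, 1)) * 0.3, requires_grad=True)
        assert_grad_matches(
            lambda: (conv2d(self.x, w, None) ** 2.0).sum(), self.x, w
        )

    def test_conv_depthwise(self):
        w = Tensor(self.rng.standard_normal((4, 1, 3, 3)) * 0.3, requires_grad=True)
        assert_grad_matches(
            lambda: conv2d(self.x, w, None, padding=1, groups=4).sum(), self.x, w
        )

    def test_max_pool(self):
        assert_grad_matches(lambda: (max_pool2d(self.x, 3) * self.mult).sum(), self.x)

    def test_batch_norm_training_mode(self):
        g = Tensor(np.ones(4), requires_grad=True)
        b = Tensor(np.zeros(4), requires_grad=True)
        assert_grad_matches(
            lambda: (
                batch_norm2d(self.x, g, b, np.zeros(4), np.ones(4), True) * self.mult
            ).sum(),
            self.x,
            g,
            b,
        )

    def test_bce_with_logits(self):
        y = (np.random.default_rng(0).uniform(size=(2, 4, 6, 6)) > 0.5).astype(
            np.float32
        )
        assert_grad_matches(lambda: bce_with_logits(self.x, y).mean(), self.x)

    def test_space_to_depth_and_upsample(self):
        assert_grad_matches(lambda: (space_to_depth2(self.x) ** 2.0).sum(), self.x)
        assert_grad_matches(lambda: (upsample_nearest2x(self.x) ** 2.0).sum(), self.x)

    def test_softmax_and_spatial_max(self):
        assert_grad_matches(lambda: (softmax(self.x, axis=1) * self.mult).sum(), self.x)
        m2 = Tensor(np.random.default_rng(1).standard_normal((2, 4, 1, 1)))
        assert_grad_matches(
            lambda: (self.x.max(axis=(2, 3), keepdims=True) * m2).sum(), self.x
        )

    def test_fancy_index_gather_accumulates_duplicates(self):
        x = Tensor(np.zeros((3, 4)), requires_grad=True)
        idx = (np.array([0, 0, 2]), np.array([1, 1, 3]))
        out = x[idx].sum()
        out.backward()
        assert x.grad[0, 1] == 2.0 and x.grad[2, 3] == 1.0

    def test_bce_with_logits_matches_closed_form(self):
        z = Tensor(np.array([0.0]))
        val = float(bce_with_logits(z, np.array([1.0])).data[0])
        assert val == pytest.approx(np.log(2), abs=1e-6)


def _dense_conv_params(cin, cout, k=3, bias=True):
    return cin * cout * k * k + (cout if bias else 0)


class TestBlocks:
    def setup_method(self):
        manual_seed(0)

    def test_ghost_shape_and_param_economy(self):
        blk = GhostBlock(64, 128)
        x = Tensor(np.random.default_rng(0).standard_normal((1, 64, 8, 8)))
        assert blk(x).shape == (1, 128, 8, 8)
        # cheaper than an equivalent dense 3x3 convolution
        assert count_parameters(blk) < _dense_conv_params(64, 128)

    def test_ghost_rejects_odd_output(self):
        with pytest.raises(ValueError):
            GhostBlock(16, 15)

    def test_inverted_residual_shapes_and_depthwise_params(self):
        blk = InvertedResidual(32, 32, expansion=2)
        x = Tensor(np.random.default_rng(0).standard_normal((2, 32, 8, 8)))
        assert blk(x).shape == (2, 32, 8, 8)
        # the depthwise stage holds k^2 * expanded_channels weights, no
        # cin x cout product
        assert blk.depthwise.conv.weight.data.size == 9 * 64
        assert count_parameters(blk) < _dense_conv_params(32, 32)

    def test_inverted_residual_expansion_one_degenerates(self):
        blk = InvertedResidual(16, 16, expansion=1)
        assert blk.expand is None

    def test_improved_csp_contract_and_context_path(self):
        blk = ImprovedCSP(64, 64)
        x = Tensor(np.random.default_rng(0).standard_normal((1, 64, 8, 8)))
        assert blk(x).shape == (1, 64, 8, 8)
        # the pooled-context path is spatially constant per channel
        a = blk.ghost(blk.pre(x))
        ctx = a.mean(axis=(2, 3), keepdims=True) * Tensor(np.ones((1, 1, 8, 8)))
        assert np.allclose(ctx.data, ctx.data[:, :, :1, :1], atol=1e-6)

    def test_improved_csp_param_count_near_baseline(self):
        base = C3(64, 64, n=1, shortcut=False)
        imp = ImprovedCSP(64, 64)
        ratio = count_parameters(imp) / count_parameters(base)
        assert abs(ratio - 1.0) < 0.5

    def test_epsa_contract(self):
        blk = EPSA(64)
        x = Tensor(np.random.default_rng(0).standard_normal((2, 64, 6, 6)))
        assert blk(x).shape == (2, 64, 6, 6)

    def test_epsa_zero_input_gives_zero(self):
        blk = EPSA(32)
        for m in blk.modules():
            m.training = False
        out = blk(Tensor(np.zeros((1, 32, 5, 5))))
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_epsa_rejects_indivisible_channels(self):
        with pytest.raises(ValueError):
            EPSA(30)

    def test_cam_contract(self):
        blk = CAM(32, 32, 32)
        rng = np.random.default_rng(0)
        s = Tensor(rng.standard_normal((1, 32, 8, 8)))
        d = Tensor(rng.standard_normal((1, 32, 8, 8)))
        assert blk(s, d).shape == (1, 32, 8, 8)

    def test_cam_zero_input_gives_zero(self):
        blk = CAM(32, 32, 32)
        for m in blk.modules():
            m.training = False
        z = Tensor(np.zeros((1, 32, 8, 8)))
        assert np.allclose(blk(z, z).data, 0.0, atol=1e-6)

    def test_cam_requires_aligned_spatial_dims(self):
        blk = CAM(32, 32, 32)
        s = Tensor(np.zeros((1, 32, 8, 8)))
        d = Tensor(np.zeros((1, 32, 4, 4)))
        with pytest.raises(ValueError):
            blk(s, d)

    def test_focus_and_spp_shapes(self):
        x = Tensor(np.random.default_rng(0).standard_normal((1, 3, 16, 16)))
        assert Focus(3, 16)(x).shape == (1, 16, 8, 8)
        y = Tensor(np.random.default_rng(0).standard_normal((1, 32, 4, 4)))
        assert SPP(32, 32)(y).shape == (1, 32, 4, 4)

    def test_eval_mode_forward_deterministic(self):
        blk = Sequential(GhostBlock(8, 16), InvertedResidual(16, 16), EPSA(16))
        for m in blk.modules():
            m.training = False
        x = Tensor(np.random.default_rng(0).standard_normal((1, 8, 8, 8)))
        a, b = blk(x), blk(x)
        assert np.array_equal(a.data, b.data)


class TestCountParameters:
    def test_single_conv_closed_form(self):
        manual_seed(0)
        conv = Conv2d(3, 16, k=3, bias=True)
        assert count_parameters(conv) == 3 * 3 * 3 * 16 + 16 == 448

    def test_empty_module_is_zero(self):
        class Empty(Module):
            def forward(self, x):
                return x

        assert count_parameters(Empty()) == 0
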
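import numpy as np
import pytest

from glioscope.nn import (
    BlockSpec,
    Conv2D,
    MBConvWeights,
    MnasLite,
    ModelConfig,
    cross_entropy_grad,
    depthwise,
    expand,
    forward,
    loss_acc,
    loss_eff,
    loss_total,
    project,
    resource_cost,
    residual_add,
    squeeze_excite,
)
from glioscope.trainer import init_weights


def _weights(rng, c_in=2, e=2, k=3, c_out=2, cr=1):
    ce = c_in * e
    return MBConvWeights(
        we=rng.normal(size=(c_in, ce)),
        be=rng.normal(size=ce),
        wdw=rng.normal(size=(k, k, ce)),
        bdw=rng.normal(size=ce),
        w1=rng.normal(size=(ce, cr)),
        b1=rng.normal(size=cr),
        w2=rng.normal(size=(cr, ce)),
        b2=rng.normal(size=ce),
        wp=rng.normal(size=(ce, c_out)),
        bp=rng.normal(size=c_out),
    )


class TestExpand:
    def test_identity(self, rng):
        w = _weights(rng, c_in=2, e=1)
        w.we = np.eye(2)
        w.be = np.zeros(2)
        x = rng.normal(size=(3, 3, 2))
        assert np.allclose(expand(x, w), x)

    def test_zero_input_gives_bias(self, rng):
        w = _weights(rng)
        out = expand(np.zeros((2, 2, 2)), w)
        assert np.allclose(out, w.be)

    def test_hand_computed_1x1(self, rng):
        # 1x1 spatial input, 2 -> 4 channels, explicit matrix arithmetic
        we = np.array([[1.0, 2.0, 0.0, -1.0], [0.5, 0.0, 3.0, 1.0]])
        be = np.array([0.1, 0.2, 0.3, 0.4])
        w = _weights(rng, c_in=2, e=2)
        w.we, w.be = we, be
        x = np.array([[[2.0, -1.0]]])
        expected = np.array([2 * 1 + (-1) * 0.5, 2 * 2 + 0, 0 + (-1) * 3, -2 - 1]) + be
        assert np.allclose(expand(x, w)[0, 0], expected)

    def test_channel_mismatch(self, rng):
        w = _weights(rng)
        with pytest.raises(ValueError):
            expand(np.zeros((2, 2, 5)), w)


class TestDepthwise:
    def test_delta_kernel_identity(self, rng):
        w = _weights(rng, e=1)
        w.wdw = np.zeros((3, 3, 2))
        w.wdw[1, 1, :] = 1.0
        w.bdw = np.zeros(2)
        x = rng.normal(size=(5, 5, 2))
        assert np.allclose(depthwise(x, w), x)

    def test_ones_kernel_constant_image(self, rng):
        w = _weights(rng, e=1)
        w.wdw = np.ones((3, 3, 2))
        w.bdw = np.zeros(2)
        v = 1.5
        out = depthwise(np.full((6, 6, 2), v), w)
        assert np.allclose(out[1:-1, 1:-1], 9 * v)  # interior
        assert np.allclose(out[0, 0], 4 * v)  # corner sees 2x2 support

    def test_bias_only(self, rng):
        w = _weights(rng, e=1)
        w.wdw = np.zeros((3, 3, 2))
        w.bdw = np.array([0.7, -0.2])
        out = depthwise(rng.normal(size=(4, 4, 2)), w)
        assert np.allclose(out, w.bdw)

    def test_even_kernel_rejected(self, rng):
        w = _weights(rng, e=1)
        w.wdw = np.ones((2, 2, 2))
        with pytest.raises(ValueError):
            depthwise(np.zeros((4, 4, 2)), w)


class TestSqueezeExcite:
    def test_zero_gate_weights_halve(self, rng):
        w = _weights(rng)
        w.w2 = np.zeros_like(w.w2)
        w.b2 = np.zeros_like(w.b2)
        x = rng.normal(size=(3, 3, 4))
        assert np.allclose(squeeze_excite(x, w), 0.5 * x)

    def test_saturated_gate_identity(self, rng):
        w = _weights(rng)
        w.b2 = np.full_like(w.b2, 50.0)
        x = rng.normal(size=(3, 3, 4))
        assert np.allclose(squeeze_excite(x, w), x, atol=1e-10)

    def test_hand_computed_single_channel(self, rng):
        # 2x2 single-channel map; scalar arithmetic oracle
        w = _weights(rng, c_in=1, e=1, cr=1)
        w.w1 = np.array([[2.0]])
        w.b1 = np.array([0.5])
        w.w2 = np.array([[1.5]])
        w.b2 = np.array([-1.0])
        x = np.array([[[1.0], [2.0]], [[3.0], [2.0]]])
        s = 2.0  # mean
        h = max(2.0 * s + 0.5, 0.0)
        g = 1.0 / (1.0 + np.exp(-(1.5 * h - 1.0)))
        assert np.allclose(squeeze_excite(x, w), g * x)


class TestProjectResidual:
    def test_zero_projection_skip_identity(self, rng):
        x = rng.normal(size=(3, 3, 2))
        assert np.allclose(residual_add(np.zeros_like(x), x), x)

    def test_zero_input(self, rng):
        xp = rng.normal(size=(3, 3, 2))
        assert np.allclose(residual_add(xp, np.zeros_like(xp)), xp)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            residual_add(rng.normal(size=(3, 3, 2)), rng.normal(size=(3, 3, 4)))

    def test_project_affine(self, rng):
        w = _weights(rng)
        x = rng.normal(size=(2, 2, 4))
        out = project(x, w)
        assert np.allclose(out, np.einsum("hwe,eo->hwo", x, w.wp) + w.bp)

    def test_stride2_block_skips_residual(self):
        from glioscope.nn.model import MBConvBlock

        blk = MBConvBlock(4, BlockSpec(expansion=2, kernel=3, stride=2, out_channels=4))
        assert not blk.residual


class TestForward:
    def test_zero_weights_uniform_probs(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(4, 8, 8, 1))
        probs = forward(tiny_model, x)
        assert np.allclose(probs, 0.5)

    def test_rows_sum_to_one(self, tiny_model_config):
        model = MnasLite(tiny_model_config, seed=0)
        init_weights(model, "he_normal", 3)
        probs = forward(model, np.random.default_rng(1).normal(size=(5, 8, 8, 1)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_wrong_input_size(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward_logits(np.zeros((2, 9, 9, 1)))

    def test_one_block_model_matches_naive_oracle(self):
        """Batched layer path vs an independent nested-loop re-implementation."""
        cfg = ModelConfig(
            input_hw=(4, 4),
            in_channels=1,
            stem_channels=2,
            blocks=(BlockSpec(expansion=2, kernel=3, stride=1, out_channels=2, se_ratio=2),),
            n_classes=2,
            dropout=0.0,
        )
        model = MnasLite(cfg, seed=0)
        rng = np.random.default_rng(5)
        for _, layer in model.param_layers():
            for key in layer.params:
                layer.params[key] = rng.normal(size=layer.params[key].shape) * 0.5
        x = rng.normal(size=(1, 4, 4, 1))

        logits = model.forward_logits(x, training=False)[0]
        expected = _naive_forward(model, x[0])
        assert np.allclose(logits, expected, atol=1e-10)


def _naive_conv(x, W, b, stride=1):
    """Plain-loop same-padded convolution oracle, independent of the layers."""
    k = W.shape[0]
    h, w, ci = x.shape
    co = W.shape[3]
    pad = k // 2
    xp = np.zeros((h + 2 * pad, w + 2 * pad, ci))
    xp[pad : pad + h, pad : pad + w] = x
    ho, wo = -(-h // stride), -(-w // stride)
    out = np.zeros((ho, wo, co))
    for oy in range(ho):
        for ox in range(wo):
            for oc in range(co):
                acc = b[oc]
                for ky in range(k):
                    for kx in range(k):
                        for ic in range(ci):
                            acc += xp[oy * stride + ky, ox * stride + kx, ic] * W[ky, kx, ic, oc]
                out[oy, ox, oc] = acc
    return out


def _naive_forward(model, img):
    stem = model.stem.params
    y = _naive_conv(img, stem["W"], stem["b"])
    y = np.maximum(y, 0.0)
    blk = model.blocks[0]
    xin = y
    # expand (1x1) + relu
    e = np.einsum("hwc,ce->hwe", xin, blk.expand.params["W"][0, 0]) + blk.expand.params["b"]
    e = np.maximum(e, 0.0)
    # depthwise + relu
    kdw = blk.dw.params["W"]
    d = np.zeros_like(e)
    k = kdw.shape[0]
    pad = k // 2
    h, w, c = e.shape
    ep = np.zeros((h + 2 * pad, w + 2 * pad, c))
    ep[pad : pad + h, pad : pad + w] = e
    for oy in range(h):
        for ox in range(w):
            for ch in range(c):
                acc = blk.dw.params["b"][ch]
                for ky in range(k):
                    for kx in range(k):
                        acc += ep[oy + ky, ox + kx, ch] * kdw[ky, kx, ch]
                d[oy, ox, ch] = acc
    d = np.maximum(d, 0.0)
    # squeeze-excitation
    s = d.mean(axis=(0, 1))
    hdd = np.maximum(s @ blk.se.params["W1"] + blk.se.params["b1"], 0.0)
    g = 1.0 / (1.0 + np.exp(-(hdd @ blk.se.params["W2"] + blk.se.params["b2"])))
    d = d * g
    # project + residual
    p = np.einsum("hwe,eo->hwo", d, blk.project.params["W"][0, 0]) + blk.project.params["b"]
    if blk.residual:
        p = p + xin
    # head
    feat = p.mean(axis=(0, 1))
    return feat @ model.head.params["W"] + model.head.params["b"]


class TestLossAcc:
    def test_perfect_prediction(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss_acc(probs, np.array([0, 1])) == 0.0

    def test_uniform_two_class(self):
        probs = np.full((4, 2), 0.5)
        assert loss_acc(probs, np.array([0, 1, 0, 1])) == pytest.approx(
            0.6931471805599453, abs=1e-12
        )

    def test_mean_of_two_samples(self):
        probs = np.array([[1.0, 0.0], [np.exp(-2.0), 1 - np.exp(-2.0)]])
        assert loss_acc(probs, np.array([0, 0])) == pytest.approx(1.0, abs=1e-12)

    def test_nonnegative_and_zero_iff_perfect(self, rng):
        probs = rng.dirichlet(np.ones(3), size=20)
        labels = rng.integers(0, 3, size=20)
        val = loss_acc(probs, labels)
        assert val >= 0.0

    def test_zero_probability_clamped(self):
        probs = np.array([[0.0, 1.0]])
        val = loss_acc(probs, np.array([0]))
        assert np.isfinite(val)


class TestResourceCost:
    def test_single_1x1_conv_param_count(self):
        conv = Conv2D(1, 4, 8)
        assert sum(p.size for p in conv.params.values()) == 40  # 4*8 + 8

    def test_analytic_matches_actual(self):
        for cfg in (
            ModelConfig(),
            ModelConfig(
                input_hw=(16, 16),
                stem_channels=4,
                blocks=(BlockSpec(expansion=2, kernel=3, stride=2, out_channels=8),),
            ),
        ):
            cost = resource_cost(cfg)
            assert cost.n_params == MnasLite(cfg).n_parameters()
            assert cost.c_size == pytest.approx(cost.n_params / 1e6)

    def test_weight_invariance_and_reproducibility(self):
        cfg = ModelConfig()
        a, b = resource_cost(cfg), resource_cost(cfg)
        assert a == b
        assert a.c_latency > 0

    def test_loss_eff_and_total(self):
        cost = resource_cost(ModelConfig())
        assert loss_eff(cost, 0.0, 0.0) == 0.0
        # arithmetic with the selected trade-off coefficients
        class FakeCost:
            c_latency = 10.0
            c_size = 4.0
        assert loss_total(0.5, FakeCost(), 8.7e-3, 4.2e-4) == pytest.approx(0.58868, abs=1e-12)

    def test_negative_lambda_rejected(self):
        cost = resource_cost(ModelConfig())
        with pytest.raises(ValueError):
            loss_eff(cost, -0.1, 0.0)
        with pytest.raises(ValueError):
            loss_total(0.1, cost, 0.0, -1.0)


class TestGradients:
    def test_finite_difference_matches_analytic(self, tiny_model_config):
        model = MnasLite(tiny_model_config, seed=0)
        rng = np.random.default_rng(0)
        init_weights(model, "xavier_normal", 1)
        # random biases avoid exact-zero ReLU pre-activations, where the
        # subgradient and the central difference legitimately disagree
        for _, layer in model.param_layers():
            for key in layer.params:
                if key.startswith("b"):
                    layer.params[key] = rng.normal(0.0, 0.1, size=layer.params[key].shape)
        x = rng.normal(size=(3, 8, 8, 1))
        y = np.array([0, 1, 0])

        def loss():
            return cross_entropy_grad(model.forward_logits(x, training=False), y)[0]

        _, dlogits = cross_entropy_grad(model.forward_logits(x, training=False), y)
        model.backward(dlogits)
        eps = 1e-5
        for name, layer in model.param_layers():
            for key in layer.params:
                p, g = layer.params[key], layer.grads[key]
                for _ in range(4):
                    idx = tuple(rng.integers(0, s) for s in p.shape)
                    orig = p[idx]
                    p[idx] = orig + eps
                    lp = loss()
                    p[idx] = orig - eps
                    lm = loss()
                    p[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    rel = abs(fd - g[idx]) / max(1e-6, abs(fd) + abs(g[idx]))
                    assert rel < 1e-4, f"{name}.{key}: rel err {rel}"
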
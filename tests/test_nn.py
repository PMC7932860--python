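"""CNN engine correctness: finite-difference gradient checks and op contracts.

Every differentiable operation is checked against central finite differences
in float64 on tiny tensors; the composite networks then inherit correctness
from the op set plus the graph traversal, which is exercised end-to-end in
the training tests.
"""

import numpy as np
import pytest

from vacuoquant.nn import (
    Adam,
    BatchNorm,
    ResNetClassifier,
    Tensor,
    UNet,
    add,
    concat_channels,
    conv2d,
    global_avg_pool,
    linear,
    maxpool2,
    relu,
    sigmoid,
    soft_dice_loss,
    softmax,
    softmax_cross_entropy,
    upsample2,
)

RNG = np.random.default_rng(12345)


def _numeric_grad(f, x, eps=1e-6):
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


def _scalar_sum_sq(out: Tensor) -> Tensor:
    s = Tensor((out.data**2).sum(), parents=(out,))
    s._backward = lambda g: out._accumulate(2 * out.data * g)
    return s


class TestGradients:
    def test_conv2d_wrt_input_weights_bias(self):
        x = RNG.normal(size=(2, 3, 6, 6))
        w = RNG.normal(size=(4, 3, 3, 3))
        b = RNG.normal(size=4)

        def run():
            tx = Tensor(x, requires_grad=True)
            tw = Tensor(w, requires_grad=True)
            tb = Tensor(b, requires_grad=True)
            return _scalar_sum_sq(conv2d(tx, tw, tb)), tx, tw, tb

        loss, tx, tw, tb = run()
        loss.backward()
        for tensor, array in ((tx, x), (tw, w), (tb, b)):
            numeric = _numeric_grad(lambda: float(run()[0].data), array)
            assert np.allclose(tensor.grad, numeric, atol=1e-5)

    @pytest.mark.parametrize(
        "op",
        [maxpool2, upsample2, relu, sigmoid, global_avg_pool],
        ids=["maxpool", "upsample", "relu", "sigmoid", "gap"],
    )
    def test_elementwise_and_pooling_ops(self, op):
        x = RNG.normal(size=(2, 3, 4, 4))

        def run():
            tx = Tensor(x, requires_grad=True)
            return _scalar_sum_sq(op(tx)), tx

        loss, tx = run()
        loss.backward()
        numeric = _numeric_grad(lambda: float(run()[0].data), x)
        assert np.allclose(tx.grad, numeric, atol=1e-5)

    def test_batchnorm_training_mode(self):
        x = RNG.normal(size=(3, 2, 4, 4))
        bn = BatchNorm(2, dtype=np.float64)
        bn.gamma.data = RNG.normal(size=2)
        bn.beta.data = RNG.normal(size=2)

        def run():
            tx = Tensor(x, requires_grad=True)
            return _scalar_sum_sq(bn(tx, train=True)), tx

        loss, tx = run()
        loss.backward()
        numeric = _numeric_grad(lambda: float(run()[0].data), x)
        assert np.allclose(tx.grad, numeric, atol=1e-5)

    def test_soft_dice_and_cross_entropy_losses(self):
        x = RNG.normal(size=(2, 1, 4, 4))
        target = (RNG.random((2, 1, 4, 4)) > 0.5).astype(float)

        def run_dice():
            tx = Tensor(x, requires_grad=True)
            return soft_dice_loss(sigmoid(tx), target), tx

        loss, tx = run_dice()
        loss.backward()
        numeric = _numeric_grad(lambda: float(run_dice()[0].data), x)
        assert np.allclose(tx.grad, numeric, atol=1e-5)

        logits = RNG.normal(size=(4, 2))
        labels = np.array([0, 1, 1, 0])

        def run_ce():
            tl = Tensor(logits, requires_grad=True)
            return softmax_cross_entropy(tl, labels), tl

        loss, tl = run_ce()
        loss.backward()
        numeric = _numeric_grad(lambda: float(run_ce()[0].data), logits)
        assert np.allclose(tl.grad, numeric, atol=1e-5)

    def test_structural_ops(self):
        a = RNG.normal(size=(2, 2, 4, 4))
        b = RNG.normal(size=(2, 3, 4, 4))
        w = RNG.normal(size=(5, 3))
        bias = RNG.normal(size=3)

        def run():
            ta = Tensor(a, requires_grad=True)
            tb = Tensor(b, requires_grad=True)
            cat = concat_channels(ta, tb)
            doubled = add(cat, cat)
            pooled = global_avg_pool(doubled)
            return _scalar_sum_sq(linear(pooled, Tensor(w, requires_grad=True), Tensor(bias))), ta, tb

        loss, ta, tb = run()
        loss.backward()
        for tensor, array in ((ta, a), (tb, b)):
            numeric = _numeric_grad(lambda: float(run()[0].data), array)
            assert np.allclose(tensor.grad, numeric, atol=1e-5)


class TestForwardContracts:
    def test_maxpool_and_upsample_values(self):
        x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
        pooled = maxpool2(Tensor(x)).data
        assert np.array_equal(pooled[0, 0], [[5, 7], [13, 15]])
        up = upsample2(Tensor(pooled)).data
        assert up.shape == (1, 1, 4, 4)
        assert np.array_equal(up[0, 0, :2, :2], [[5, 5], [5, 5]])

    def test_softmax_rows_normalize(self):
        probs = softmax(RNG.normal(size=(10, 2)) * 50)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert probs.min() >= 0

    def test_unet_output_shape_and_range(self):
        net = UNet(base_filters=4, depth=2, seed=0)
        out = net.forward(RNG.random((2, 3, 16, 16)).astype(np.float32))
        assert out.data.shape == (2, 1, 16, 16)
        assert out.data.min() >= 0 and out.data.max() <= 1

    def test_unet_rejects_indivisible_size(self):
        net = UNet(base_filters=4, depth=3, seed=0)
        with pytest.raises(ValueError):
            net.forward(RNG.random((1, 3, 18, 18)).astype(np.float32))

    def test_resnet_logits_shape_and_feature_exposure(self):
        net = ResNetClassifier(base_filters=4, blocks_per_stage=(1, 1), seed=0)
        logits, feat = net.forward(RNG.random((3, 3, 16, 16)).astype(np.float32))
        assert logits.data.shape == (3, 2)
        assert feat.data.shape[0] == 3 and feat.data.ndim == 4

    def test_state_roundtrip_preserves_predictions(self):
        net = ResNetClassifier(base_filters=4, blocks_per_stage=(1, 1), seed=0)
        x = RNG.random((2, 3, 16, 16)).astype(np.float32)
        before, _ = net.forward(x)
        state = [a.copy() for a in net.state_arrays()]
        fresh = ResNetClassifier(base_filters=4, blocks_per_stage=(1, 1), seed=99)
        fresh.load_state_arrays(state)
        after, _ = fresh.forward(x)
        assert np.array_equal(before.data, after.data)


def test_adam_descends_a_quadratic():
    p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        p.grad = 2 * p.data
        opt.step()
    assert np.abs(p.data).max() < 1e-2
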
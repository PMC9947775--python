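"""Layer-level checks: convolution against an independent oracle, and
finite-difference gradient verification for every layer type."""

import numpy as np
import pytest
from scipy import ndimage

from hcnet.nn import (
    Adam,
    BatchNorm,
    Conv,
    ConvTranspose,
    MaxPool,
    Parameter,
    ReLU,
    conv_forward,
    softmax,
)


class TestConvForward:
    def test_matches_scipy_correlate_single_channel(self, rng):
        """Single-channel stride-1 conv equals scipy's zero-padded correlation."""
        for rank, k in [(2, (3, 3)), (3, (3, 3, 3))]:
            x = rng.standard_normal((1, 1) + (7,) * rank)
            w = rng.standard_normal((1, 1) + k)
            got = conv_forward(x, w, (1,) * rank, (1,) * rank)[0, 0]
            want = ndimage.correlate(x[0, 0], w[0, 0], mode="constant")
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_multichannel_matches_loop(self, rng):
        """Channel mixing equals an explicit loop over in/out channels."""
        x = rng.standard_normal((2, 3, 6, 6))
        w = rng.standard_normal((4, 3, 3, 3))
        got = conv_forward(x, w, (1, 1), (1, 1))
        want = np.zeros((2, 4, 6, 6))
        for n in range(2):
            for co in range(4):
                for ci in range(3):
                    want[n, co] += ndimage.correlate(x[n, ci], w[co, ci], mode="constant")
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_strided(self, rng):
        """Stride-2 output picks every other stride-1 output position."""
        x = rng.standard_normal((1, 2, 8, 8))
        w = rng.standard_normal((3, 2, 3, 3))
        full = conv_forward(x, w, (1, 1), (1, 1))
        strided = conv_forward(x, w, (2, 2), (1, 1))
        np.testing.assert_allclose(strided, full[:, :, ::2, ::2], atol=1e-12)


class TestTransposeConv:
    @pytest.mark.parametrize(
        "rank,kernel,stride,size",
        [(2, (4, 4), (2, 2), 5), (3, (3, 4, 4), (1, 2, 2), 4)],
    )
    def test_output_size_law(self, rng, rank, kernel, stride, size):
        layer = ConvTranspose(2, 3, kernel, stride=stride, pad=1, rank=rank,
                              rng=rng, dtype=np.float64)
        x = rng.standard_normal((1, 2) + (size,) * rank)
        y = layer.forward(x)
        want = tuple(st * (size - 1) + k - 2 for st, k in zip(stride, kernel))
        assert y.shape == (1, 3) + want

    def test_adjoint_identity(self, rng):
        """<conv(x), y> == <x, conv_transpose(y)> with shared weights."""
        conv = Conv(3, 2, 4, stride=2, pad=1, rank=2, rng=rng, dtype=np.float64)
        tconv = ConvTranspose(2, 3, 4, stride=2, pad=1, rank=2, rng=rng, dtype=np.float64)
        # conv weight (Co=2, Ci=3, k, k) == transpose-conv weight (Cin=2, Cout=3, k, k)
        tconv.w.value = conv.w.value.copy()
        conv.b.value[...] = 0.0
        tconv.b.value[...] = 0.0
        x = rng.standard_normal((1, 3, 8, 8))
        y = rng.standard_normal((1, 2, 4, 4))
        lhs = np.sum(conv.forward(x) * y)
        rhs = np.sum(x * tconv.forward(y))
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)


class TestMaxPool:
    def test_known_values(self):
        x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        y = MaxPool((2, 2)).forward(x)
        np.testing.assert_array_equal(y[0, 0], [[5, 7], [13, 15]])

    def test_depth_preserving_window(self, rng):
        x = rng.standard_normal((2, 3, 3, 8, 8))
        y = MaxPool((1, 2, 2)).forward(x)
        assert y.shape == (2, 3, 3, 4, 4)

    def test_indivisible_raises(self, rng):
        with pytest.raises(ValueError, match="not divisible"):
            MaxPool((2, 2)).forward(rng.standard_normal((1, 1, 5, 4)))


def _finite_diff_check(layer, x_shape, rng, training_stats=False, atol=1e-6):
    """Compare analytic input/parameter gradients with central differences."""
    x = rng.standard_normal(x_shape)
    gout = rng.standard_normal(layer.forward(x, training=True).shape)

    def loss(inp):
        return float(np.sum(layer.forward(inp, training=True) * gout))

    layer.forward(x, training=True)
    for p in layer.parameters():
        p.zero_grad()
    dx = layer.backward(gout)

    eps = 1e-6
    # input gradient at a handful of positions
    flat = x.reshape(-1)
    for idx in rng.choice(flat.size, size=5, replace=False):
        old = flat[idx]
        flat[idx] = old + eps
        lp = loss(x)
        flat[idx] = old - eps
        lm = loss(x)
        flat[idx] = old
        np.testing.assert_allclose(dx.reshape(-1)[idx], (lp - lm) / (2 * eps),
                                   atol=atol, rtol=1e-4)
    # parameter gradients
    for p in layer.parameters():
        pf = p.value.reshape(-1)
        for idx in rng.choice(pf.size, size=min(5, pf.size), replace=False):
            old = pf[idx]
            pf[idx] = old + eps
            lp = loss(x)
            pf[idx] = old - eps
            lm = loss(x)
            pf[idx] = old
            np.testing.assert_allclose(p.grad.reshape(-1)[idx], (lp - lm) / (2 * eps),
                                       atol=atol, rtol=1e-4)


@pytest.mark.parametrize(
    "make,shape",
    [
        (lambda r: Conv(2, 3, 3, pad=1, rank=2, rng=r, dtype=np.float64), (2, 2, 6, 6)),
        (lambda r: Conv(2, 3, 3, pad=1, rank=3, rng=r, dtype=np.float64), (2, 2, 3, 5, 5)),
        (lambda r: ConvTranspose(3, 2, 4, stride=2, pad=1, rank=2, rng=r, dtype=np.float64), (2, 3, 4, 4)),
        (lambda r: ConvTranspose(3, 2, (3, 4, 4), stride=(1, 2, 2), pad=1, rank=3, rng=r, dtype=np.float64), (1, 3, 3, 4, 4)),
        (lambda r: BatchNorm(3, dtype=np.float64), (4, 3, 5, 5)),
        (lambda r: BatchNorm(2, dtype=np.float64), (3, 2, 3, 4, 4)),
        (lambda r: MaxPool((2, 2)), (2, 3, 6, 6)),
        (lambda r: MaxPool((1, 2, 2)), (2, 2, 3, 4, 4)),
        (lambda r: ReLU(), (2, 3, 5, 5)),
    ],
    ids=["conv2d", "conv3d", "tconv2d", "tconv3d", "bn4d", "bn5d",
         "pool2d", "pool3d", "relu"],
)
def test_layer_gradients_match_finite_differences(make, shape, rng):
    _finite_diff_check(make(rng), shape, rng)


class TestBatchNorm:
    def test_training_normalizes_batch(self, rng):
        bn = BatchNorm(4, dtype=np.float64)
        x = rng.standard_normal((8, 4, 6, 6)) * 3 + 1
        y = bn.forward(x, training=True)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0, atol=1e-10)
        np.testing.assert_allclose(y.var(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_eval_uses_running_stats(self, rng):
        bn = BatchNorm(2, dtype=np.float64)
        x = rng.standard_normal((16, 2, 4, 4)) * 2 + 5
        for _ in range(200):
            bn.forward(x, training=True)
        y = bn.forward(x, training=False)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0, atol=0.05)


def test_adam_decreases_quadratic(rng):
    p = Parameter(rng.standard_normal(10))
    opt = Adam([p], lr=0.1)
    for _ in range(200):
        opt.zero_grad()
        p.grad += 2 * p.value
        opt.step()
    assert np.abs(p.value).max() < 1e-2


def test_softmax_normalizes(rng):
    x = rng.standard_normal((3, 4, 5))
    s = softmax(x, axis=1)
    np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)
    assert (s > 0).all()
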
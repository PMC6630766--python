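"""Numeric kernels of the autodiff core against independent oracles."""

import numpy as np
import pytest
from scipy.signal import correlate

from paraseg import nn
from paraseg.nn import autodiff as ad


def _numeric_grad(fn, arrays, index, idx, eps=1e-6):
    """Central finite difference of fn(*arrays) w.r.t. arrays[index][idx]."""
    plus = [a.copy() for a in arrays]
    minus = [a.copy() for a in arrays]
    plus[index][idx] += eps
    minus[index][idx] -= eps
    return (fn(*plus) - fn(*minus)) / (2 * eps)


class TestConv2d:
    def test_forward_matches_scipy_correlate(self, rng):
        x = rng.normal(size=(2, 3, 9, 9))
        w = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        out = ad.conv2d(ad.Tensor(x), ad.Tensor(w), ad.Tensor(b)).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for n in range(2):
            for o in range(4):
                ref = sum(correlate(xp[n, c], w[o, c], mode="valid")
                          for c in range(3)) + b[o]
                np.testing.assert_allclose(out[n, o], ref, atol=1e-12)

    @pytest.mark.parametrize("stride,k", [(1, 3), (2, 3), (2, 7), (2, 5)])
    def test_strided_shapes(self, rng, stride, k):
        x = ad.Tensor(rng.normal(size=(1, 2, 16, 16)))
        w = ad.Tensor(rng.normal(size=(5, 2, k, k)))
        out = ad.conv2d(x, w, None, stride=stride)
        assert out.shape == (1, 5, 16 // stride, 16 // stride)

    def test_gradients_match_finite_differences(self, rng):
        x = rng.normal(size=(2, 2, 6, 6))
        w = rng.normal(size=(3, 2, 3, 3))
        b = rng.normal(size=3)
        g = rng.normal(size=(2, 3, 3, 3))
        xt, wt, bt = (ad.Tensor(a, requires_grad=True) for a in (x, w, b))
        ad.conv2d(xt, wt, bt, stride=2).backward(g)

        def value(xa, wa, ba):
            return float((ad.conv2d(ad.Tensor(xa), ad.Tensor(wa),
                                    ad.Tensor(ba), stride=2).data * g).sum())

        for i, (arr, tens) in enumerate([(x, xt), (w, wt), (b, bt)]):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            fd = _numeric_grad(value, [x, w, b], i, idx)
            assert tens.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestBatchNorm:
    def test_train_mode_normalises(self, rng):
        x = rng.normal(loc=3.0, scale=2.0, size=(4, 2, 5, 5))
        bn = nn.BatchNorm2d(2)
        y = bn(ad.Tensor(x.astype(np.float32))).data
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_backward_matches_finite_differences(self, rng):
        x = rng.normal(size=(3, 2, 4, 4))
        gamma, beta = np.array([1.3, 0.7]), np.array([0.1, -0.2])
        g = rng.normal(size=x.shape)
        xt = ad.Tensor(x, requires_grad=True)
        gt = ad.Tensor(gamma, requires_grad=True)
        bt = ad.Tensor(beta, requires_grad=True)
        ad.batch_norm2d(xt, gt, bt, np.zeros(2), np.ones(2),
                        training=True).backward(g)

        def value(xa, ga, ba):
            return float((ad.batch_norm2d(
                ad.Tensor(xa), ad.Tensor(ga), ad.Tensor(ba),
                np.zeros(2), np.ones(2), training=True).data * g).sum())

        for i, (arr, tens) in enumerate([(x, xt), (gamma, gt), (beta, bt)]):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            fd = _numeric_grad(value, [x, gamma, beta], i, idx)
            assert tens.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_eval_mode_uses_running_stats(self, rng):
        bn = nn.BatchNorm2d(1)
        x = rng.normal(size=(2, 1, 4, 4)).astype(np.float32)
        bn(ad.Tensor(x))          # one training pass updates buffers
        bn.eval()
        y = bn(ad.Tensor(x)).data
        expected = (x - bn.running_mean[0]) / np.sqrt(bn.running_var[0] + bn.eps)
        np.testing.assert_allclose(y, expected, atol=1e-5)


class TestBilinearResize:
    def test_constant_preserved_and_adjoint(self, rng):
        ones = ad.bilinear_resize(ad.Tensor(np.ones((1, 1, 8, 8))), 20, 20)
        np.testing.assert_allclose(ones.data, 1.0, atol=1e-12)
        # <A x, g> == <x, A^T g>: backward is the exact adjoint
        x = rng.normal(size=(1, 1, 8, 8))
        g = rng.normal(size=(1, 1, 20, 20))
        xt = ad.Tensor(x, requires_grad=True)
        ad.bilinear_resize(xt, 20, 20).backward(g)
        lhs = (ad.bilinear_resize(ad.Tensor(x), 20, 20).data * g).sum()
        rhs = (x * xt.grad).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_linear_ramp_reproduced_in_interior(self):
        ramp = np.arange(8, dtype=float)[None, None, None, :] * np.ones((1, 1, 8, 1))
        up = ad.bilinear_resize(ad.Tensor(ramp), 8, 16).data[0, 0, 0]
        interior = up[2:-2]
        expected = (np.arange(16)[2:-2] + 0.5) * 0.5 - 0.5
        np.testing.assert_allclose(interior, expected, atol=1e-12)


class TestElementwise:
    def test_broadcast_add_backward_sums(self, rng):
        a = ad.Tensor(rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        b = ad.Tensor(rng.normal(size=(2, 3, 1, 1)), requires_grad=True)
        g = rng.normal(size=(2, 3, 4, 4))
        ad.add(a, b).backward(g)
        np.testing.assert_allclose(b.grad, g.sum(axis=(2, 3), keepdims=True))
        np.testing.assert_allclose(a.grad, g)

    def test_mul_and_relu_grads(self, rng):
        a = ad.Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        b = ad.Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        ad.relu(ad.mul(a, b)).backward(np.ones((3, 3)))
        mask = (a.data * b.data) > 0
        np.testing.assert_allclose(a.grad, b.data * mask)
        np.testing.assert_allclose(b.grad, a.data * mask)

    def test_concat_splits_gradient(self, rng):
        a = ad.Tensor(rng.normal(size=(1, 2, 3, 3)), requires_grad=True)
        b = ad.Tensor(rng.normal(size=(1, 3, 3, 3)), requires_grad=True)
        g = rng.normal(size=(1, 5, 3, 3))
        ad.concat([a, b], axis=1).backward(g)
        np.testing.assert_allclose(a.grad, g[:, :2])
        np.testing.assert_allclose(b.grad, g[:, 2:])


class TestDiceLossOp:
    def test_gradient_matches_finite_differences(self, rng):
        p = rng.uniform(0.01, 0.99, size=(2, 1, 6, 6))
        g = (rng.random((2, 1, 6, 6)) > 0.5).astype(float)
        pt = ad.Tensor(p, requires_grad=True)
        ad.soft_dice_loss(pt, g).backward()
        idx = (1, 0, 3, 2)
        fd = _numeric_grad(
            lambda pa: float(ad.soft_dice_loss(ad.Tensor(pa), g).data), [p], 0, idx,
            eps=1e-7)
        assert pt.grad[idx] == pytest.approx(fd, rel=1e-4)

    def test_value_range(self, rng):
        p = rng.uniform(size=(3, 1, 4, 4))
        g = (rng.random((3, 1, 4, 4)) > 0.5).astype(float)
        val = float(ad.soft_dice_loss(ad.Tensor(p), g).data)
        assert -1.0 <= val <= 0.0


def test_no_grad_builds_no_graph(rng):
    x = ad.Tensor(rng.normal(size=(1, 1, 4, 4)), requires_grad=True)
    with ad.no_grad():
        y = ad.relu(x)
    assert y._parents == () and y._backward is None


def test_sgd_momentum_update_rule():
    p = nn.Parameter(np.array([1.0]))
    opt = nn.SGD([p], momentum=0.9)
    p.grad = np.array([2.0], dtype=np.float32)
    opt.step(0.1)          # v = -0.2 ; w = 0.8
    assert p.data[0] == pytest.approx(0.8)
    p.grad = np.array([0.0], dtype=np.float32)
    opt.step(0.1)          # v = -0.18 ; w = 0.62
    assert p.data[0] == pytest.approx(0.62)


def test_state_dict_round_trip(rng):
    a = nn.Conv2d(1, 2, 3, rng=np.random.default_rng(0))
    b = nn.Conv2d(1, 2, 3, rng=np.random.default_rng(99))
    assert not np.array_equal(a.weight.data, b.weight.data)
    b.load_state_dict(a.state_dict())
    np.testing.assert_array_equal(a.weight.data, b.weight.data)
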
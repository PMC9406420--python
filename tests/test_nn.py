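"""Autodiff engine: finite-difference gradient checks and op contracts."""

import numpy as np
import pytest

from consegnet.nn import Adam, Parameter, Tensor, backward
from consegnet.nn import functional as F
from consegnet.errors import ShapeError


def _numgrad(f, arr, eps=2e-3):
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


def _relerr(a, b):
    return np.abs(a - b).max() / (np.abs(b).max() + 1e-8)


class TestGradients:
    """Every backward closure matches central finite differences."""

    def test_conv_bn_pool_unpool_sigmoid_iou_chain(self, rng):
        x = Parameter(rng.normal(0, 1, (2, 4, 4, 2)).astype(np.float32))
        w = Parameter(rng.normal(0, 0.5, (3, 3, 2, 3)).astype(np.float32))
        b = Parameter(rng.normal(0, 0.1, 3).astype(np.float32))
        gamma = Parameter(np.ones(3, np.float32))
        beta = Parameter(np.zeros(3, np.float32))
        target = (rng.random((2, 4, 4, 3)) > 0.5).astype(np.float32)
        rm = np.zeros(3, np.float32)
        rv = np.ones(3, np.float32)

        def forward():
            y = F.conv2d(x, w, b)
            y = F.batchnorm2d(y, gamma, beta, rm.copy(), rv.copy(), training=True)
            y = F.relu(y)
            p, idx = F.maxpool2x2(y)
            y2 = F.maxunpool2x2(p, idx)
            return F.soft_iou_loss(F.sigmoid(y2), target)

        loss = forward()
        backward(loss)
        for p in (x, w, gamma, beta):
            analytic = p.grad.copy()
            numeric = _numgrad(lambda: float(forward().data), p.data)
            assert _relerr(analytic, numeric) < 0.02

    def test_dilated_conv_gradients(self, rng):
        x = Parameter(rng.normal(0, 1, (1, 6, 6, 2)).astype(np.float32))
        w = Parameter(rng.normal(0, 0.5, (3, 3, 2, 2)).astype(np.float32))
        b = Parameter(np.zeros(2, np.float32))
        t = rng.normal(0, 1, (1, 6, 6, 2)).astype(np.float32)

        def forward():
            y = F.conv2d(x, w, b, dilation=2)
            return F.soft_iou_loss(F.sigmoid(y), (t > 0).astype(np.float32))

        loss = forward()
        backward(loss)
        for p in (x, w, b):
            numeric = _numgrad(lambda: float(forward().data), p.data)
            assert _relerr(p.grad, numeric) < 0.02

    def test_concat_and_clip_gradients(self, rng):
        a = Parameter(rng.normal(0, 1, (1, 2, 2, 2)).astype(np.float32))
        b = Parameter(rng.normal(0, 1, (1, 2, 2, 1)).astype(np.float32))
        g = (rng.random((1, 2, 2, 3)) > 0.5).astype(np.float32)

        def forward():
            return F.soft_iou_loss(F.clip01(F.concat(a, b)), g)

        loss = forward()
        backward(loss)
        for p in (a, b):
            numeric = _numgrad(lambda: float(forward().data), p.data)
            # clip01 has kinks at 0/1; compare only where no coordinate crosses
            assert _relerr(p.grad, numeric) < 0.05

    def test_shared_tensor_accumulates_from_both_consumers(self, rng):
        # y used twice (concat with a transform of itself) sums both gradient paths
        x = Parameter(rng.normal(0, 1, (1, 2, 2, 1)).astype(np.float32))
        w = Parameter(rng.normal(0, 0.5, (1, 1, 1, 1)).astype(np.float32))
        b = Parameter(np.zeros(1, np.float32))
        g = np.ones((1, 2, 2, 2), np.float32)

        def forward():
            t = F.conv2d(x, w, b)
            return F.soft_iou_loss(F.sigmoid(F.concat(x, t)), g)

        loss = forward()
        backward(loss)
        numeric = _numgrad(lambda: float(forward().data), x.data)
        assert _relerr(x.grad, numeric) < 0.02


class TestOps:
    def test_maxpool_known_grid(self):
        # 4x4 values 1..16 row-major: window maxima are 6, 8, 14, 16
        x = Tensor(np.arange(1, 17, dtype=np.float32).reshape(1, 4, 4, 1))
        y, idx = F.maxpool2x2(x)
        assert np.array_equal(y.data[0, :, :, 0], [[6, 8], [14, 16]])
        assert (idx == 3).all()  # bottom-right of each window

    def test_maxpool_tie_break_first_row_major(self):
        x = Tensor(np.ones((1, 2, 2, 1), np.float32))
        y, idx = F.maxpool2x2(x)
        assert y.data[0, 0, 0, 0] == 1.0
        assert idx[0, 0, 0, 0] == 0  # first occurrence in row-major window order

    def test_odd_dims_rejected(self):
        with pytest.raises(ShapeError):
            F.maxpool2x2(Tensor(np.zeros((1, 3, 4, 1), np.float32)))

    def test_unpool_shape_mismatch_rejected(self, rng):
        p = Tensor(rng.random((1, 2, 2, 1)).astype(np.float32))
        with pytest.raises(ShapeError):
            F.maxunpool2x2(p, np.zeros((1, 3, 3, 1), np.int8))

    def test_batchnorm_normalizes_batch(self, rng):
        x = Tensor(rng.normal(3.0, 2.0, (4, 8, 8, 3)).astype(np.float32))
        gamma = Parameter(np.ones(3, np.float32))
        beta = Parameter(np.zeros(3, np.float32))
        y = F.batchnorm2d(x, gamma, beta, np.zeros(3, np.float32),
                          np.ones(3, np.float32), training=True)
        assert np.abs(y.data.mean(axis=(0, 1, 2))).max() < 1e-4
        assert np.abs(y.data.std(axis=(0, 1, 2)) - 1).max() < 1e-3

    def test_adam_descends_quadratic(self):
        p = Parameter(np.array([5.0, -3.0], np.float32))
        opt = Adam([p], lr=0.1)
        for _ in range(500):
            p.zero_grad()
            p.grad = 2 * p.data  # d/dp sum(p^2)
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_inference_mode_records_no_tape(self, rng):
        from consegnet.nn import no_grad
        x = Parameter(rng.random((1, 2, 2, 1)).astype(np.float32))
        with no_grad():
            y = F.relu(x)
        assert y._backward is None and not y.requires_grad
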
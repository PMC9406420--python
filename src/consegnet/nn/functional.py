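"""Fused forward/backward ops on NHWC float32 tensors.

Convolution is computed as im2col + one BLAS matmul per layer (taps gathered
by slicing the padded input, so dilation is just a larger tap offset).
Max pooling uses a fixed 2x2/stride-2 window and records per-window argmax
indices in row-major window order (first occurrence wins ties); unpooling
scatters values back to exactly those positions.  All backward closures were
derived by hand and are covered by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError, DataError, ShapeError
from .tensor import Tensor, make_op, needs_grad, grad_enabled

__all__ = ["conv2d", "relu", "clip01", "sigmoid", "batchnorm2d",
           "maxpool2x2", "maxunpool2x2", "concat", "soft_iou_loss", "as_tensor"]


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=x.dtype)
    xp[:, pad:pad + h, pad:pad + w, :] = x
    return xp


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Gather kxk taps (spacing ``dilation``) into (N*H*W, k*k*C) columns."""
    n, h, w, c = x.shape
    pad = dilation * (k // 2)
    xp = _pad_spatial(x, pad)
    cols = np.empty((n, h, w, k * k, c), dtype=x.dtype)
    t = 0
    for i in range(k):
        for j in range(k):
            cols[:, :, :, t, :] = xp[:, i * dilation:i * dilation + h,
                                     j * dilation:j * dilation + w, :]
            t += 1
    return cols.reshape(n * h * w, k * k * c)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, dilation: int) -> np.ndarray:
    """Scatter-add column gradients back to the input grid (adjoint of _im2col)."""
    n, h, w, c = shape
    pad = dilation * (k // 2)
    gxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    dcols = dcols.reshape(n, h, w, k * k, c)
    t = 0
    for i in range(k):
        for j in range(k):
            gxp[:, i * dilation:i * dilation + h, j * dilation:j * dilation + w, :] += dcols[:, :, :, t, :]
            t += 1
    if pad == 0:
        return gxp
    return gxp[:, pad:-pad, pad:-pad, :]


def conv2d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-padding 2D convolution; weights shaped (k, k, C_in, C_out)."""
    if dilation < 1:
        raise ConfigError(f"dilation must be >= 1, got {dilation}")
    k = w.data.shape[0]
    if x.data.ndim != 4:
        raise ShapeError(f"conv2d expects NHWC input, got shape {x.data.shape}")
    if x.data.shape[-1] != w.data.shape[2]:
        raise ShapeError(f"conv2d channel mismatch: input {x.data.shape[-1]} vs weight {w.data.shape[2]}")
    n, h, wd, cin = x.data.shape
    cout = w.data.shape[3]
    wmat = w.data.reshape(k * k * cin, cout)

    if k == 1:
        xm = x.data.reshape(-1, cin)
        y = xm @ wmat + b.data
        cols = None
    else:
        cols = _im2col(x.data, k, dilation)
        y = cols @ wmat + b.data
    y = y.reshape(n, h, wd, cout)

    keep_cols = cols if grad_enabled() and needs_grad(w) else None
    xm_cache = x.data if k == 1 else None

    def backward_fn(gy: np.ndarray) -> None:
        gym = gy.reshape(-1, cout)
        if needs_grad(b):
            b.accumulate(gym.sum(axis=0))
        if needs_grad(w):
            src = xm_cache.reshape(-1, cin) if k == 1 else keep_cols
            w.accumulate((src.T @ gym).reshape(w.data.shape))
        if needs_grad(x):
            if k == 1:
                x.accumulate((gym @ wmat.T).reshape(x.data.shape))
            else:
                # tap-wise accumulation into the padded gradient: same FLOPs as
                # one big (NHW, k*k*C) product but no large temporary
                pad = dilation * (k // 2)
                gxp = np.zeros((n, h + 2 * pad, wd + 2 * pad, cin), dtype=np.float32)
                wr = w.data.reshape(k * k, cin, cout)
                t = 0
                for i in range(k):
                    for j in range(k):
                        gxp[:, i * dilation:i * dilation + h,
                            j * dilation:j * dilation + wd, :] += (
                            gym @ wr[t].T).reshape(n, h, wd, cin)
                        t += 1
                x.accumulate(gxp[:, pad:-pad, pad:-pad, :] if pad else gxp)

    return make_op(y, (x, w, b), backward_fn)


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)

    def backward_fn(gy):
        if needs_grad(x):
            x.accumulate(gy * (x.data > 0))

    return make_op(y, (x,), backward_fn)


def clip01(x: Tensor) -> Tensor:
    """ReLU additionally capped at 1: elementwise min(max(x,0),1)."""
    y = np.clip(x.data, 0.0, 1.0)

    def backward_fn(gy):
        if needs_grad(x):
            x.accumulate(gy * ((x.data > 0) & (x.data < 1)))

    return make_op(y, (x,), backward_fn)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def backward_fn(gy):
        if needs_grad(x):
            x.accumulate(gy * y * (1.0 - y))

    return make_op(y, (x,), backward_fn)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, momentum: float = 0.9,
                eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over the (N, H, W) axes.

    In training mode the batch statistics normalize and the running
    estimates are updated in place; in inference mode the running
    estimates are used, making the op a fixed affine map.
    """
    c = x.data.shape[-1]
    m = x.data.size // c
    if training:
        flat = x.data.reshape(-1, c)
        mu = flat.mean(axis=0)
        var = np.einsum("ij,ij->j", flat, flat) / m - mu * mu
        np.maximum(var, 0.0, out=var)
        running_mean *= momentum
        running_mean += (1.0 - momentum) * mu
        running_var *= momentum
        running_var += (1.0 - momentum) * var * (m / max(m - 1, 1))  # unbiased for inference
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    y = gamma.data * xhat + beta.data

    def backward_fn(gy):
        gyf = gy.reshape(-1, c)
        xhf = xhat.reshape(-1, c)
        dgamma = np.einsum("ic,ic->c", gyf, xhf)
        dbeta = gyf.sum(axis=0)
        if needs_grad(gamma):
            gamma.accumulate(dgamma)
        if needs_grad(beta):
            beta.accumulate(dbeta)
        if needs_grad(x):
            if training:
                x.accumulate(gamma.data * inv_std
                             * (gy - dbeta / m - xhat * (dgamma / m)))
            else:
                x.accumulate(gy * gamma.data * inv_std)

    return make_op(y if y.dtype == np.float32 else y.astype(np.float32),
                   (x, gamma, beta), backward_fn)


def _window_view(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return (x.reshape(n, h // 2, 2, w // 2, 2, c)
             .transpose(0, 1, 3, 2, 4, 5)
             .reshape(n, h // 2, w // 2, 4, c))


def maxpool2x2(x: Tensor) -> tuple[Tensor, np.ndarray]:
    """2x2/stride-2 max pooling; returns (pooled, indices).

    ``indices`` holds, per output cell and channel, the argmax position
    0..3 within its 2x2 window in row-major order (ties -> first).
    """
    n, h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ShapeError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    win = _window_view(x.data)
    idx = win.argmax(axis=3).astype(np.int8)
    y = np.take_along_axis(win, idx[:, :, :, None, :].astype(np.int64), axis=3)[:, :, :, 0, :]

    def backward_fn(gy):
        if needs_grad(x):
            gwin = np.zeros((n, h // 2, w // 2, 4, c), dtype=gy.dtype)
            np.put_along_axis(gwin, idx[:, :, :, None, :].astype(np.int64),
                              gy[:, :, :, None, :], axis=3)
            gx = (gwin.reshape(n, h // 2, w // 2, 2, 2, c)
                      .transpose(0, 1, 3, 2, 4, 5)
                      .reshape(n, h, w, c))
            x.accumulate(gx)

    return make_op(y, (x,), backward_fn), idx


def maxunpool2x2(x: Tensor, idx: np.ndarray) -> Tensor:
    """Scatter pooled values back to their recorded argmax positions; zeros elsewhere."""
    n, h, w, c = x.data.shape
    if idx.shape != (n, h, w, c):
        raise ShapeError(f"unpool indices shape {idx.shape} does not match input {x.data.shape}")
    win = np.zeros((n, h, w, 4, c), dtype=x.data.dtype)
    np.put_along_axis(win, idx[:, :, :, None, :].astype(np.int64),
                      x.data[:, :, :, None, :], axis=3)
    y = (win.reshape(n, h, w, 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, 2 * h, 2 * w, c))

    def backward_fn(gy):
        if needs_grad(x):
            gwin = _window_view(gy)
            gx = np.take_along_axis(gwin, idx[:, :, :, None, :].astype(np.int64),
                                    axis=3)[:, :, :, 0, :]
            x.accumulate(gx)

    return make_op(y, (x,), backward_fn)


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two NHWC tensors along channels."""
    if a.data.shape[:-1] != b.data.shape[:-1]:
        raise ShapeError(f"concat spatial mismatch: {a.data.shape} vs {b.data.shape}")
    ca = a.data.shape[-1]
    y = np.concatenate([a.data, b.data], axis=-1)

    def backward_fn(gy):
        if needs_grad(a):
            a.accumulate(gy[..., :ca])
        if needs_grad(b):
            b.accumulate(gy[..., ca:])

    return make_op(y, (a, b), backward_fn)


def soft_iou_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Differentiable IoU (Jaccard) loss, averaged over the batch.

    Per sample: ``1 - (sum(p*g) + eps) / (sum(p) + sum(g) - sum(p*g) + eps)``.
    Zero exactly when a binary prediction equals the target; near 1 for
    disjoint nonempty sets.
    """
    g = np.asarray(target, dtype=np.float32)
    if g.shape != pred.data.shape:
        raise ShapeError(f"loss shape mismatch: pred {pred.data.shape} vs target {g.shape}")
    if not np.all(np.isfinite(pred.data)):
        raise DataError("soft_iou_loss: non-finite predictions")
    nb = pred.data.shape[0]
    axes = tuple(range(1, pred.data.ndim))
    inter = (pred.data * g).sum(axis=axes)
    union = pred.data.sum(axis=axes) + g.sum(axis=axes) - inter
    frac = (inter + eps) / (union + eps)
    loss = np.float32(1.0 - frac.mean())

    def backward_fn(gl):
        if needs_grad(pred):
            shape = (nb,) + (1,) * (pred.data.ndim - 1)
            u = (union + eps).reshape(shape)
            i = (inter + eps).reshape(shape)
            # d(-I/U)/dp = -[g*U - I*(1-g)] / U^2
            gp = -(g * u - i * (1.0 - g)) / (u * u) / nb
            pred.accumulate(gl.reshape(()) * gp)

    return make_op(loss, (pred,), backward_fn)
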
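"""SegNet layer primitives on single H x W x C feature maps.

Thin functional wrappers over the tensor engine for the building blocks the
architecture is made of: the conv+ReLU+BN unit, 2x2 max pooling with argmax
index recording, index-driven max unpooling, the [0,1]-capped "advanced
ReLU", and dilated same-padding convolution.  These operate on plain NumPy
arrays (one sample, channels last) and are what the assembled network uses
batch-wise internally.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, ShapeError
from .nn import functional as F
from .nn.layers import Conv2d, ConvBlock
from .nn.tensor import Tensor, no_grad

__all__ = ["conv_block", "max_pool_indices", "unpool_indices",
           "advanced_relu", "dilated_conv"]


def _as_nhwc(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ShapeError(f"expected an HxWxC feature map, got shape {x.shape}")
    return x[None]


def conv_block(x: np.ndarray, filters: int, repeats: int = 2,
               seed: int = 0) -> np.ndarray:
    """Apply ``repeats`` x (3x3 conv -> ReLU -> BN) with seeded He-normal weights.

    Spatial dims are preserved (same padding); output has ``filters`` channels.
    """
    xb = _as_nhwc(x)
    block = ConvBlock(xb.shape[-1], filters, repeats,
                      rng=np.random.default_rng(seed))
    with no_grad():
        y = block.forward(Tensor(xb))
    return y.data[0]


def max_pool_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2/stride-2 max pool; returns (pooled, argmax indices 0..3 per window)."""
    xb = _as_nhwc(x)
    with no_grad():
        y, idx = F.maxpool2x2(Tensor(xb))
    return y.data[0], idx[0]


def unpool_indices(pooled: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Place each pooled value at its recorded window position; zeros elsewhere."""
    pb = _as_nhwc(pooled)
    idx = np.asarray(indices)
    if idx.ndim == 2:
        idx = idx[:, :, None]
    with no_grad():
        y = F.maxunpool2x2(Tensor(pb), idx[None])
    return y.data[0]


def advanced_relu(x: np.ndarray) -> np.ndarray:
    """Elementwise min(max(x, 0), 1): ReLU with the activation capped at 1."""
    return np.clip(np.asarray(x, dtype=np.float32), 0.0, 1.0)


def dilated_conv(x: np.ndarray, filters: int, dilation: int = 3,
                 seed: int = 0) -> np.ndarray:
    """Same-padding 3x3 convolution with taps spaced ``dilation`` pixels apart."""
    if dilation < 1:
        raise ConfigError(f"dilation must be >= 1, got {dilation}")
    xb = _as_nhwc(x)
    conv = Conv2d(xb.shape[-1], filters, k=3, dilation=dilation,
                  rng=np.random.default_rng(seed))
    with no_grad():
        y = conv.forward(Tensor(xb))
    return y.data[0]
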
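"""Minimal reverse-mode autodiff over NumPy arrays.

Only what an index-unpooling encoder-decoder needs: a ``Tensor`` holding a
float32 array, a tape of fused ops (convolution, batch norm, pooling,
unpooling, concatenation, activations, IoU loss) each of which registers a
single backward closure, and a topological-order ``backward`` walk.  A
``no_grad`` context disables taping for inference so forward passes allocate
nothing beyond the activations.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "grad_enabled", "backward",
           "make_op", "needs_grad"]

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """A float32 array plus an optional backward closure on the tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True) if g.dtype != np.float32 else g.copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None


class Parameter(Tensor):
    """A trainable tensor (weight, bias, BN scale/shift)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def make_op(out_data: np.ndarray, parents: tuple[Tensor, ...], backward_fn) -> Tensor:
    """Wrap an op result; ``backward_fn(grad_out)`` must accumulate into parents."""
    out = Tensor(out_data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad or p._backward is not None)
        out._backward = backward_fn
    return out


def backward(loss: Tensor) -> None:
    """Reverse-mode sweep from a scalar loss through the recorded tape."""
    if loss.data.size != 1:
        raise ValueError("backward expects a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))

    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
            node.grad = None  # intermediate: free once propagated; leaves keep theirs


def needs_grad(t: Tensor) -> bool:
    """True if a gradient must be propagated into ``t`` (leaf param or taped op)."""
    return t.requires_grad or t._backward is not None
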
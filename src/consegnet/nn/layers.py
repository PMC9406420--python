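"""Layer modules: parameter containers over the functional ops.

A ``Module`` tracks named submodules/parameters recursively, supports
train/eval mode, and round-trips its state through a flat ``{name: array}``
dict for checkpointing.  Weight initialization is He-normal from an explicit
``numpy.random.Generator`` so model construction is fully seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError
from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock"]


class Module:
    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module") -> None:
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield f"{prefix}{k}", b
        for name, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{name}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=np.float32).reshape(params[k].data.shape)
            elif k in buffers:
                buffers[k][...] = v
            else:
                raise ConfigError(f"unknown checkpoint entry {k!r}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise ConfigError(f"checkpoint missing entries: {sorted(missing)[:5]} ...")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Same-padding kxk convolution, He-normal init."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if cout < 1:
            raise ConfigError(f"filters must be >= 1, got {cout}")
        if dilation < 1:
            raise ConfigError(f"dilation must be >= 1, got {dilation}")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * cin))
        self.weight = Parameter(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.bias = Parameter(np.zeros(cout))
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class ConvBlock(Module):
    """``repeats`` x (3x3 conv -> ReLU -> BN), the encoder/decoder unit.

    The conv -> ReLU -> BN order follows the architecture as published;
    ``bn_before_relu=True`` swaps to the more common conv -> BN -> ReLU
    for ablation.
    """

    def __init__(self, cin: int, cout: int, repeats: int,
                 rng: np.random.Generator | None = None,
                 bn_before_relu: bool = False, dilation: int = 1):
        super().__init__()
        if repeats < 1:
            raise ConfigError(f"repeats must be >= 1, got {repeats}")
        self.repeats = repeats
        self.bn_before_relu = bn_before_relu
        for i in range(repeats):
            self.add_module(f"conv{i}", Conv2d(cin if i == 0 else cout, cout,
                                               dilation=dilation, rng=rng))
            self.add_module(f"bn{i}", BatchNorm2d(cout))

    def forward(self, x: Tensor) -> Tensor:
        for i in range(self.repeats):
            x = self._modules[f"conv{i}"].forward(x)
            if self.bn_before_relu:
                x = F.relu(self._modules[f"bn{i}"].forward(x))
            else:
                x = self._modules[f"bn{i}"].forward(F.relu(x))
        return x
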
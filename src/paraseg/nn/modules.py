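"""Layer abstractions over the autodiff core: parameters, conv, batch norm.

Modules own named parameters (and non-trainable buffers such as batch-norm
running statistics) and compose recursively, so a whole network can be
serialised to / restored from a flat ``{dotted.name: array}`` state dict.
Weight initialisation follows the Xavier (Glorot) uniform scheme and is
driven by an explicit ``numpy.random.Generator`` so that model construction
is reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data: np.ndarray) -> None:
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: named parameters/buffers, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
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

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialisation ---------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers.items():
            out[prefix + name] = b.copy()
        for mname, m in self._modules.items():
            out.update(m.state_dict(prefix + mname + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._params.items():
            p.data = np.asarray(state[prefix + name], dtype=DTYPE).reshape(p.data.shape)
        for name in self._buffers:
            arr = np.asarray(state[prefix + name])
            self._buffers[name][...] = arr.reshape(self._buffers[name].shape)
        for mname, m in self._modules.items():
            m.load_state_dict(state, prefix + mname + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv2d(Module):
    """Square-kernel 2-D convolution with 'same'-style padding (k // 2)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = in_channels * k * k
        fan_out = out_channels * k * k
        self.weight = Parameter(
            xavier_uniform((out_channels, in_channels, k, k), fan_in, fan_out, rng))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.batch_norm2d(x, self.gamma, self.beta,
                               self.running_mean, self.running_var,
                               training=self.training, momentum=self.momentum,
                               eps=self.eps)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SGD:
    """Stochastic gradient descent with classical momentum.

    Velocity update ``v <- momentum * v - lr * grad; w <- w + v``, matching
    the Keras-style optimiser the training protocol assumes.
    """

    def __init__(self, params, momentum: float = 0.9) -> None:
        self.params = list(params)
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= lr * p.grad.astype(p.data.dtype)
            p.data = p.data + v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
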
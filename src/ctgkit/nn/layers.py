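"""Module/parameter system and the standard layers built on the autodiff core."""

from __future__ import annotations

import numpy as np

from . import core
from .core import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight container with recursive parameter discovery."""

    def __init__(self) -> None:
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def walk(self):
        """This module and all descendants, depth-first."""
        yield self
        for m in self.modules():
            yield from m.walk()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{path}.{i}.")
                    elif isinstance(v, Parameter):
                        yield f"{path}.{i}", v

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self):
        self.training = True
        for m in self.modules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out[name] = buf.copy()
        return out

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_buffers(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_buffers(f"{path}.{i}.")

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float32).copy()
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name}")

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_out: int) -> np.ndarray:
    std = float(np.sqrt(2.0 / fan_out))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dilation: int = 1, groups: int = 1):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_out = out_ch * kernel * kernel // groups
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch // groups, kernel, kernel), fan_out))

    def forward(self, x):
        return core.conv2d(x, self.weight, self.stride, self.padding,
                           self.dilation, self.groups)


class BatchNorm(Module):
    """Batch normalization over all axes but channel axis 1 (2-D or 4-D input)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels, np.float32))
        self.bias = Parameter(np.zeros(channels, np.float32))
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return core.batch_norm(x, self.weight, self.bias, self.running_mean,
                               self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return core.relu(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, np.float32)) if bias else None

    def forward(self, x):
        return core.linear(x, self.weight, self.bias)

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return core.max_pool2d(x, self.kernel, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int = 2):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def forward(self, x):
        return core.avg_pool2d(x, self.kernel, self.stride)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
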
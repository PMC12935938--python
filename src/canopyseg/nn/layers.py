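"""Layer modules: convolution, batch norm, linear, activations, containers."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor, conv2d

_rng = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed the global initializer RNG (parameter initialisation only)."""
    global _rng
    _rng = np.random.default_rng(seed)


def _kaiming(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return _rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Minimal module base: attribute-discovered parameters and submodules."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Module):
                yield from v.named_buffers(full + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif isinstance(v, np.ndarray) and name.startswith("running_"):
                yield full, v

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {f"buffer:{name}": (name, b) for name, b in self.named_buffers()}
        for key, value in state.items():
            if key.startswith("buffer:"):
                if key not in buffers:
                    raise KeyError(f"unknown buffer {key!r} in checkpoint")
                buffers[key][1][...] = value
            else:
                if key not in params:
                    raise KeyError(f"unknown parameter {key!r} in checkpoint")
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key!r}: {params[key].data.shape} vs {value.shape}")
                params[key].data = value.astype(params[key].data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_ch // groups) * kernel * kernel
        self.weight = Parameter(_kaiming((out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation, self.groups)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming((in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size // C
            self.running_mean += self.momentum * (mu.data.reshape(C) - self.running_mean)
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
            xhat = xc * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean.reshape(1, C, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, C, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Hardswish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hardswish()


class Hardsigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.hardsigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def parameter_count(module: Module) -> int:
    """Exact number of learnable scalars in ``module``."""
    return int(sum(p.data.size for p in module.parameters()))
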
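"""Module system and standard layers built on the autograd Tensor."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv2d",
    "Conv1d",
    "DepthwiseCausalConv1d",
    "BatchNorm1d",
    "BatchNorm2d",
]

DTYPE = np.float32


class Module:
    """Base class with recursive parameter/buffer discovery.

    Sub-modules and parameters are discovered through instance attributes, so
    plain attribute assignment is all that is needed to register them.
    """

    def __init__(self):
        self.training = True

    # -- registry ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and not value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(prefix=full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{full}.{i}.")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data for name, p in self.named_parameters()}
        d.update({name: b.data for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        own.update(dict(self.named_buffers()))
        missing = set(own) - set(d)
        extra = set(d) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, t in own.items():
            arr = np.asarray(d[name])
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            t.data = arr.astype(t.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(
            _kaiming_uniform(rng, (in_features, out_features), in_features),
            requires_grad=True,
        )
        self.bias = (
            Tensor(_kaiming_uniform(rng, (out_features,), in_features), requires_grad=True)
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(_kaiming_uniform(rng, (out_ch,), fan_in), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_ch, in_ch, kernel), fan_in), requires_grad=True
        )
        self.bias = Tensor(_kaiming_uniform(rng, (out_ch,), fan_in), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.weight, self.bias)


class DepthwiseCausalConv1d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(
            _kaiming_uniform(rng, (channels, kernel), kernel), requires_grad=True
        )
        self.bias = Tensor(_kaiming_uniform(rng, (channels,), kernel), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_causal_conv1d(x, self.weight, self.bias)


class _BatchNorm(Module):
    """Batch normalization over all axes except the channel axis."""

    def __init__(self, channels: int, channel_axis: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.channel_axis = channel_axis
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = Tensor(np.zeros(channels, dtype=DTYPE))
        self.running_var = Tensor(np.ones(channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(i for i in range(x.ndim) if i != self.channel_axis)
        bshape = [1] * x.ndim
        bshape[self.channel_axis] = -1
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean.data = (
                (1 - m) * self.running_mean.data + m * mean.data.reshape(-1)
            ).astype(DTYPE)
            self.running_var.data = (
                (1 - m) * self.running_var.data + m * var.data.reshape(-1)
            ).astype(DTYPE)
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        else:
            mean = Tensor(self.running_mean.data.reshape(bshape))
            var = Tensor(self.running_var.data.reshape(bshape))
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class BatchNorm1d(_BatchNorm):
    """For (B, C, P) inputs."""

    def __init__(self, channels: int, **kw):
        super().__init__(channels, channel_axis=1, **kw)


class BatchNorm2d(_BatchNorm):
    """For (B, C, H, W) inputs."""

    def __init__(self, channels: int, **kw):
        super().__init__(channels, channel_axis=1, **kw)
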
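"""Layer abstractions over the tensor engine.

Mirrors the familiar Module API at the scale this package needs: modules
hold named parameters and buffers, expose train/eval mode, and support
state-dict round-trips for checkpointing.
"""

from __future__ import annotations

import math

import numpy as np

from .functional import avg_pool2d, conv2d, same_padding
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "DepthwiseConv2d", "BatchNorm2d",
           "Dropout2d", "Sequential", "Identity", "AvgPool2d"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    # -- modes & state ------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.named_children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for key, arr in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                *path, leaf = name.split(".")
                obj = self
                for part in path:
                    obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
                getattr(obj, leaf)[...] = arr
            else:
                params[key].data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def __getitem__(self, i):
        return self.mods[i]

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Conv2d(Module):
    """Dense 2-D convolution with per-side "same" padding by default."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        bound = math.sqrt(2.0 / fan_in)  # Kaiming-normal for post-SiLU layers
        self.weight = Parameter(rng.normal(0.0, bound, size=(c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.padding = (same_padding(k), same_padding(k)) if stride == 1 else (((k - 1) // 2, (k - 1) // 2),) * 2

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=1)


class DepthwiseConv2d(Module):
    """Depthwise convolution with a possibly rectangular (kh, kw) kernel."""

    def __init__(self, channels: int, kh: int, kw: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(2.0 / (kh * kw))
        self.weight = Parameter(rng.normal(0.0, bound, size=(channels, 1, kh, kw)))
        self.bias = Parameter(np.zeros(channels)) if bias else None
        self.channels = channels
        self.padding = (same_padding(kh), same_padding(kw))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return conv2d(x, self.weight, self.bias, stride=1,
                      padding=self.padding, groups=self.channels)


class BatchNorm2d(Module):
    """Batch normalisation with running statistics (momentum 0.1)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var

        m = mean.reshape(1, -1, 1, 1)
        inv = (1.0 / np.sqrt(var + self.eps)).reshape(1, -1, 1, 1).astype(x.data.dtype)
        xhat = (x.data - m) * inv
        out = xhat * self.gamma.data.reshape(1, -1, 1, 1) + self.beta.data.reshape(1, -1, 1, 1)
        training = self.training

        def backward(g):
            gam = self.gamma.data.reshape(1, -1, 1, 1)
            if self.gamma.requires_grad:
                self.gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if self.beta.requires_grad:
                self.beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                if training:
                    # full batch-norm backward (mean and var depend on x)
                    N = g.shape[0] * g.shape[2] * g.shape[3]
                    gx_hat = g * gam
                    t1 = gx_hat - gx_hat.mean(axis=(0, 2, 3), keepdims=True)
                    t2 = xhat * (gx_hat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                    x._accum(inv * (t1 - t2))
                else:
                    x._accum(g * gam * inv)

        return Tensor._wrap(out.astype(x.data.dtype), (x, self.gamma, self.beta), backward)


class Dropout2d(Module):
    """Channelwise dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float = 0.0, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = (self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.rate)
        scale = keep.astype(x.data.dtype) / (1.0 - self.rate)
        return x * Tensor(scale)


class AvgPool2d(Module):
    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool2d(x, self.k)
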
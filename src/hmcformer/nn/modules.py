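"""Module/parameter containers for the numpy NN core.

Modules hold :class:`Parameter` leaves and child modules as attributes;
``named_parameters`` walks the attribute tree (including lists) the same way
the mainstream frameworks do.  Weight init follows the Swin/ConvNeXt
convention: truncated normal (std 0.02) for all conv/linear weights, zeros
for biases, ones/zeros for norm affine parameters.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +/- 2 std (resampled)."""
    x = rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.standard_normal(bad.sum()) * std
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    # -- attribute walking -------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if name.startswith("_") or name == "training":
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)[:5]} "
                           f"unexpected={sorted(unexpected)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(
            trunc_normal(rng, (out_ch, in_ch, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class LayerNorm(Module):
    """Layer norm over the trailing (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ChannelLayerNorm(LayerNorm):
    """Layer norm over the channel axis of an NCHW map (ConvNeXt style)."""

    def forward(self, x):
        xt = x.transpose(0, 2, 3, 1)
        yt = F.layer_norm(xt, self.weight, self.bias, self.eps)
        return yt.transpose(0, 3, 1, 2)


class Mlp(Module):
    """Two-layer perceptron with GELU, as used inside transformer blocks."""

    def __init__(self, dim: int, hidden: int, rng, out_dim: int | None = None):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim or dim, rng)

    def forward(self, x):
        return self.fc2(F.gelu(self.fc1(x)))


class DropPath(Module):
    """Stochastic depth: drop the residual branch per sample while training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self._rng = rng

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        mask = (self._rng.random(shape) < keep).astype(np.float32) / keep
        return F.scale_by(x, mask)
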
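"""Neural-network layers and the Adam optimizer on top of :mod:`mfnet.autodiff`.

Layers follow the familiar Module pattern: parameters are discovered by
recursing over attributes, ``state_dict``/``load_state_dict`` move weights in
and out as plain ``{name: ndarray}`` mappings, and ``train()``/``eval()``
toggle batch-norm behaviour.  All initialisation draws from an explicit
``numpy.random.Generator`` so model construction is reproducible.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: attribute-recursive parameter/buffer registry."""

    def __init__(self):
        self.training = True

    # -- registry ---------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}." if prefix else f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(
                            f"{prefix}{name}.{i}." if prefix else f"{name}.{i}.")

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mprefix, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, Parameter):
                    yield f"{mprefix}{name}", val

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for mprefix, mod in self.named_modules():
            for name in getattr(mod, "_buffers", ()):
                yield f"{mprefix}{name}", getattr(mod, name)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- mode -------------------------------------------------------------
    def train(self) -> "Module":
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for _, m in self.named_modules():
            m.training = False
        return self

    # -- serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(
                f"checkpoint mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"checkpoint mismatch: shape of {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, b in bufs.items():
            b[...] = state[name]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 2-D convolution with symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None, dilation: int = 1, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        self.padding = dilation * (kernel - 1) // 2 if padding is None else padding
        self.dilation = dilation
        fan_in = in_ch * kernel * kernel
        if zero_init:
            self.weight = Parameter(np.zeros((out_ch, in_ch, kernel, kernel),
                                             dtype=np.float32))
        else:
            self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias,
                        padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    _buffers = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return F.batchnorm2d(x, self.gamma, self.beta,
                             self.running_mean, self.running_var,
                             training=self.training,
                             momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class DeformConv2d(Module):
    """3x3 deformable convolution whose offsets come from an auxiliary 3x3 conv.

    The offset predictor is zero-initialised (weights and bias), so at
    construction the layer is numerically a standard 3x3 convolution; offsets
    are then learned jointly with the kernel.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.offset_conv = Conv2d(in_ch, 18, 3, rng, zero_init=True)
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, 3, 3), in_ch * 9))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x):
        offsets = self.offset_conv(x)
        return F.deform_conv2d(x, offsets, self.weight, self.bias)


class ConvBNReLU(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
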
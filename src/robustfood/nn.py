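"""Minimal neural-network layers and SGD on top of :mod:`robustfood.tensor`.

Layers follow the conventions of mainstream deep-learning frameworks:
``Module`` containers expose ``named_parameters()`` with stable dotted names
(used by the checkpoint format), ``train()``/``eval()`` toggle batch-norm
statistics, and initialization is He-style fan-in scaling driven by an
explicit ``numpy.random.Generator`` so every model is reproducible from a
single root seed.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Iterator

import numpy as np

from .tensor import Tensor, conv2d, relu, reshape, transpose

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "Linear",
    "BatchNorm",
    "ReLU",
    "PixelShuffle",
    "SGD",
    "adaptive_avg_pool2d",
    "pixel_shuffle",
]


class Module:
    """Base class: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_mods", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._mods.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._mods.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out = OrderedDict()
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, arr in self.named_buffers():
            out[name] = arr.copy()
        return out

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in getattr(self, "_buffers", {}).items():
            yield (prefix + name, b)
        for name, m in self._mods.items():
            yield from m.named_buffers(prefix + name + ".")

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self._iter_buffer_slots())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for '{name}': "
                        f"checkpoint {arr.shape} vs model {own[name].data.shape}")
                own[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in bufs:
                mod, key = bufs[name]
                if mod._buffers[key].shape != arr.shape:
                    raise ValueError(f"shape mismatch for buffer '{name}'")
                mod._buffers[key] = np.asarray(arr, dtype=np.float64).copy()
            else:
                raise KeyError(f"unexpected key in state dict: '{name}'")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")

    def _iter_buffer_slots(self, prefix: str = ""):
        for key in getattr(self, "_buffers", {}):
            yield prefix + key, (self, key)
        for name, m in self._mods.items():
            yield from m._iter_buffer_slots(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = list(mods)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return relu(x)


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = math.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = int(kernel_size)
        self.stride, self.padding = int(stride), int(padding)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = _param(rng, (out_channels, in_channels, k, k),
                             fan_in=in_channels * k * k)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.weight = _param(rng, (out_features, in_features), fan_in=in_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x):
        # x: (B, in) -> (B, out)
        out = x @ transpose(self.weight, None)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm(Module):
    """Batch normalization over the batch (+ spatial) axes.

    Works on (B, C) and (B, C, H, W) inputs. Training mode normalizes with
    batch statistics and updates exponential running averages; eval mode uses
    the running statistics as constants.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps, self.momentum = float(eps), float(momentum)
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        object.__setattr__(self, "_buffers", OrderedDict(
            running_mean=np.zeros(num_features),
            running_var=np.ones(num_features),
        ))

    def forward(self, x):
        nd = x.data.ndim
        if nd == 2:
            axes, shape = (0,), (1, self.num_features)
        elif nd == 4:
            axes, shape = (0, 2, 3), (1, self.num_features, 1, 1)
        else:
            raise ValueError(f"BatchNorm expects 2-d or 4-d input, got {nd}-d")
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = \
                (1 - m) * self._buffers["running_mean"] + m * mean.data.reshape(-1)
            self._buffers["running_var"] = \
                (1 - m) * self._buffers["running_var"] + m * var.data.reshape(-1)
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


def pixel_shuffle(x, upscale_factor: int = 2):
    """Sub-pixel rearrangement: (B, C*r^2, H, W) -> (B, C, rH, rW).

    Scan order: input channel ``c*r^2 + i*r + j`` fills output cell
    ``(h*r + i, w*r + j)`` of channel ``c`` (row-major within each r x r block).
    """
    r = int(upscale_factor)
    B, C2, H, W = x.data.shape
    if C2 % (r * r) != 0:
        raise ValueError(f"pixel_shuffle: {C2} channels not divisible by r^2={r * r}")
    C = C2 // (r * r)
    x = reshape(x, (B, C, r, r, H, W))
    x = transpose(x, (0, 1, 4, 2, 5, 3))  # (B, C, H, r, W, r)
    return reshape(x, (B, C, H * r, W * r))


class PixelShuffle(Module):
    def __init__(self, upscale_factor: int = 2):
        super().__init__()
        self.upscale_factor = upscale_factor

    def forward(self, x):
        return pixel_shuffle(x, self.upscale_factor)


def adaptive_avg_pool2d(x, output_size: tuple[int, int]):
    """Average-pool (B,C,H,W) to (B,C,h,w); requires h | H and w | W."""
    B, C, H, W = x.data.shape
    h, w = output_size
    if H % h or W % w:
        raise ValueError(f"adaptive_avg_pool2d: ({H},{W}) not divisible by ({h},{w})")
    fh, fw = H // h, W // w
    x = reshape(x, (B, C, h, fh, w, fw))
    return x.mean(axis=(3, 5))


class SGD:
    """Stochastic gradient descent with classical momentum and optional
    global gradient-norm clipping (stabilizes the deep restoration chains)."""

    def __init__(self, params: list[Tensor], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0,
                 max_grad_norm: float | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.max_grad_norm = max_grad_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def _clip_scale(self) -> float:
        if self.max_grad_norm is None:
            return 1.0
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        norm = math.sqrt(total)
        return 1.0 if norm <= self.max_grad_norm else self.max_grad_norm / norm

    def step(self) -> None:
        scale = self._clip_scale()
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
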
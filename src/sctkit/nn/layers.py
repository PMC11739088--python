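"""Neural-network building blocks on top of the autodiff tensor.

Conventions follow the image-translation literature: feature maps are
(B, C, H, W); token grids for attention blocks are (B, H, W, C).  Weight
initialisation is N(0, 0.02) for convolutions and projections (the standard
choice for adversarial image translation), ones/zeros for normalisation
scales/offsets.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module", "Parameter", "Sequential", "Conv2d", "Linear", "LayerNorm",
    "InstanceNorm2d", "ReLU", "LeakyReLU", "Tanh", "GELU", "upsample2x_nchw",
    "upsample2x_tokens", "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: tracks parameters through attributes and
    lists of sub-modules."""

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> List[Tuple[str, Parameter]]:
        out: List[Tuple[str, Parameter]] = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(full + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        named = dict(self.named_parameters())
        if set(named) != set(state):
            raise ValueError("checkpoint parameter names do not match the model")
        for name, p in named.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for parameter {name}")
            p.data = state[name].astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.items = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.items:
            x = m(x)
        return x


class Conv2d(Module):
    """2D convolution via sliding windows + einsum; zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: Optional[int] = None, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        if kernel % 2 == 0:
            raise ValueError("odd kernels only")
        self.stride = stride
        self.kernel = kernel
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Parameter(rng.normal(0.0, 0.02, (out_ch, in_ch, kernel, kernel)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        w, b, s, k, p = self.weight, self.bias, self.stride, self.kernel, self.padding
        if min(x.shape[-2:]) + 2 * p < k:
            raise ValueError("input smaller than the convolution kernel")
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win[:, :, ::s, ::s]  # B, Cin, Ho, Wo, k, k
        out = np.einsum("bcijyx,ocyx->boij", cols, w.data, optimize=True)
        if b is not None:
            out = out + b.data[None, :, None, None]

        x_shape = x.shape

        def backward(g):
            if w.requires_grad:
                w._accumulate(np.einsum("boij,bcijyx->ocyx", g, cols, optimize=True))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gcols = np.einsum("boij,ocyx->bcijyx", g, w.data, optimize=True)
                gxp = np.zeros_like(xp)
                ho, wo = g.shape[-2:]
                for ky in range(k):
                    for kx in range(k):
                        gxp[:, :, ky : ky + ho * s : s, kx : kx + wo * s : s] += gcols[:, :, :, :, ky, kx]
                h, wdt = x_shape[-2:]
                x._accumulate(gxp[:, :, p : p + h, p : p + wdt])

        return Tensor._op(out, (x, w) + (() if b is None else (b,)), backward)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, 0.02, (in_dim, out_dim)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape((-1, shape[-1]))
        out = flat @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(shape[:-1] + (self.weight.data.shape[1],))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, n_ch: int, eps: float = 1e-5, affine: bool = True):
        self.eps = eps
        self.gamma = Parameter(np.ones((1, n_ch, 1, 1), dtype=np.float32)) if affine else None
        self.beta = Parameter(np.zeros((1, n_ch, 1, 1), dtype=np.float32)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=(2, 3), keepdims=True)
        out = xc / ((var + self.eps) ** 0.5)
        if self.gamma is not None:
            out = out * self.gamma + self.beta
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class GELU(Module):
    """tanh approximation of the Gaussian error linear unit."""

    _C = math.sqrt(2.0 / math.pi)

    def forward(self, x: Tensor) -> Tensor:
        return x * 0.5 * ((self._C * (x + x**3 * 0.044715)).tanh() + 1.0)


def upsample2x_nchw(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of a (B, C, H, W) map."""
    b, c, h, w = x.shape
    y = x.reshape((b, c, h, 1, w, 1))
    y = y.broadcast_to((b, c, h, 2, w, 2))
    return y.reshape((b, c, 2 * h, 2 * w))


def upsample2x_tokens(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of a (B, H, W, C) token grid."""
    b, h, w, c = x.shape
    y = x.reshape((b, h, 1, w, 1, c))
    y = y.broadcast_to((b, h, 2, w, 2, c))
    return y.reshape((b, 2 * h, 2 * w, c))


class Adam:
    """Adam with the adversarial-training convention beta1 = 0.5."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
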
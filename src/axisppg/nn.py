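"""Neural-network building blocks on the package's autodiff engine.

Layers follow the familiar Module/Parameter pattern: a :class:`Module` owns
:class:`Parameter` tensors and sub-modules, exposes ``parameters()`` /
``state_dict()`` and an ``__call__`` forward.  Initialisation is
Kaiming-uniform driven by an explicit ``numpy.random.Generator`` so every
weight in a model is reproducible from one seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "Conv1d", "LayerNorm",
    "Sequential", "ReLU", "Adam",
]


DEFAULT_DTYPE = np.float32  # network precision; losses run in the target dtype


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Base class: children are discovered through instance attributes."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(v, Parameter):
                        yield f"{prefix}{name}.{i}", v

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=DEFAULT_DTYPE).copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        lead = x.shape[:-1]
        flat = x.reshape(int(np.prod(lead)) if lead else 1, x.shape[-1])
        out = flat @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out.reshape(*lead, self.weight.shape[1])


# ---- convolution -------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, ho, wo),
        (s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride))
    return win.reshape(n, c * kh * kw, ho * wo).copy(), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = xshape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d6[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation via im2col; NCHW layout."""
    cout, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[1]}, weight {cin}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    w2 = weight.data.reshape(cout, cin * kh * kw)
    out_data = np.matmul(w2, cols)           # (N, Cout, L)
    if bias is not None:
        out_data = out_data + bias.data[:, None]
    out_data = out_data.reshape(x.shape[0], cout, ho, wo)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g2 = g.reshape(x.shape[0], cout, ho * wo)
        if weight.requires_grad:
            dw = np.einsum("ncl,nkl->ck", g2, cols).reshape(weight.shape)
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, padding))

    return Tensor._make(out_data, parents, backward)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Conv1d(Module):
    """1-D convolution on (N, C, L), realised as a height-1 2-D convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming_uniform(
            rng, (out_channels, in_channels, 1, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        n, c, length = x.shape
        x4 = x.reshape(n, c, 1, length)
        out = conv2d(x4, self.weight, self.bias, stride=self.stride, padding=0) \
            if self.padding == 0 else None
        if self.padding:
            x4 = x4.pad(((0, 0), (0, 0), (0, 0), (self.padding, self.padding)))
            out = conv2d(x4, self.weight, self.bias, stride=self.stride, padding=0)
        return out.reshape(out.shape[0], out.shape[1], out.shape[3])


class LayerNorm(Module):
    """Normalises over the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def cat(tensors, axis: int = 0) -> Tensor:
    return concatenate(tensors, axis=axis)


class Adam:
    """Adam optimiser with optional decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
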
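"""Axis-projection network for rPPG estimation.

A ``(B, 3, T, H, W)`` video window is processed three times, once per axis.
For axis ``n`` the video is reshaped so that axis becomes the batch
dimension and the remaining two form a 2-D image; two stride-2 convolutions
extract a quarter-resolution feature; a reshape lays the per-slice features
out as a spatio-temporal map (rows = position along the axis, columns =
flattened space); a MaxViT-style layer (convolutional unit + windowed block
attention + grid attention) with a spatial-attention gate refines the map;
an adaptive pool and reshape produce the axis feature.  A *feature mixer* —
one of ten algebraic combinations of the three axis features (Hadamard
products, sums, a batched 4x4 matrix product, residual adds) — yields a
single ``(B, C, T, 4, 4)`` attentive feature, which a small decoder turns
into a length-``T`` signal.

Shape pipeline for the default configuration (C=3, T=32, H=W=128):

====================  =================  =================  =================
stage                 T-axis             H-axis             W-axis
====================  =================  =================  =================
project               (B*T, C, 128,128)  (B*H, C, 32, 128)  (B*W, C, 32, 128)
conv x2 (stride 2)    (B*T, C, 32, 32)   (B*H, C, 8, 32)    (B*W, C, 8, 32)
spatio-temporal map   (B, C, T, 1024)    (B, C, H, 256)     (B, C, W, 256)
MaxViT + gate         (B, C, T, 1024)    (B, C, H, 256)     (B, C, W, 256)
pool + reshape        (B, C, T, 4, 4)    (B, C, 4, H, 4)    (B, C, 4, W, 4)
====================  =================  =================  =================

H/W features are trilinearly interpolated onto ``(T, 4, 4)`` before mixing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, as_tensor, apply_matrix_last, no_grad
from . import nn

__all__ = [
    "AxisTag", "ModelConfig", "AxisFeature", "MixedFeature",
    "axis_project", "st_translate", "interp_to_T", "mix_features",
    "AxisExtractor", "PPGDecoder", "AxisProjectionNet", "count_parameters",
]

AXES = ("T", "H", "W")


@dataclass(frozen=True)
class AxisTag:
    """Which video axis plays the batch role; gives the (D1, D2, D3) order."""

    name: str

    def __post_init__(self):
        if self.name not in AXES:
            raise ValueError(f"axis must be one of {AXES}")

    def dims(self, T: int, H: int, W: int) -> tuple[int, int, int]:
        return {"T": (T, H, W), "H": (H, T, W), "W": (W, T, H)}[self.name]


@dataclass(frozen=True)
class ModelConfig:
    T: int = 32
    size: int = 128
    channels: int = 3
    mixer_case: int = 6
    attn_window: tuple[int, int] = (8, 8)
    attn_heads: int = 1
    maxvit_depth: int = 1
    decoder_hidden: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.T % 4 or self.size % 4:
            raise ValueError("T and size must be divisible by 4")
        if not 1 <= self.mixer_case <= 10:
            raise ValueError("mixer_case must be in 1..10")
        if self.channels % self.attn_heads:
            raise ValueError("channels must be divisible by attn_heads")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["attn_window"] = list(d["attn_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "attn_window" in d:
            d["attn_window"] = tuple(d["attn_window"])
        return cls(**d)


@dataclass(frozen=True)
class AxisFeature:
    tensor: Tensor
    axis: AxisTag


@dataclass(frozen=True)
class MixedFeature:
    tensor: Tensor


# ---- pure reshapes ------------------------------------------------------


def axis_project(batch, axis: AxisTag | str) -> Tensor:
    """Move the chosen axis into the batch dimension; pure reshape."""
    axis = AxisTag(axis) if isinstance(axis, str) else axis
    x = as_tensor(batch)
    if x.ndim != 5:
        raise ValueError("batch must be (B, C, T, H, W)")
    b, c, t, h, w = x.shape
    if axis.name == "T":
        y = x.transpose(0, 2, 1, 3, 4)   # (B, T, C, H, W)
        return y.reshape(b * t, c, h, w)
    if axis.name == "H":
        y = x.transpose(0, 3, 1, 2, 4)   # (B, H, C, T, W)
        return y.reshape(b * h, c, t, w)
    y = x.transpose(0, 4, 1, 2, 3)       # (B, W, C, T, H)
    return y.reshape(b * w, c, t, h)


def st_translate(x, batch_size: int) -> Tensor:
    """Lay per-slice 2-D features out as a spatio-temporal map.

    ``((B*D1), C, d2, d3) -> (B, C, D1, d2*d3)``: row index = position along
    the projected axis, column index = flattened space.
    """
    x = as_tensor(x)
    bd1, c, d2, d3 = x.shape
    if bd1 % batch_size:
        raise ValueError("leading dim not divisible by batch size")
    d1 = bd1 // batch_size
    y = x.reshape(batch_size, d1, c, d2, d3)
    y = y.transpose(0, 2, 1, 3, 4)
    return y.reshape(batch_size, c, d1, d2 * d3)


def _interp_matrix(n: int, m: int) -> np.ndarray:
    """Linear-interpolation matrix (n -> m), endpoints aligned."""
    if n == m:
        return np.eye(n)
    w = np.zeros((n, m))
    if m == 1:
        w[:, 0] = 1.0 / n
        return w
    pos = np.arange(m) * (n - 1) / (m - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    frac = pos - lo
    w[lo, np.arange(m)] += 1.0 - frac
    w[hi, np.arange(m)] += frac
    return w


def _apply_matrix_axis(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    y = x.moveaxis(axis, x.ndim - 1)
    y = apply_matrix_last(y, m)
    return y.moveaxis(y.ndim - 1, axis)


def interp_to_T(feature: AxisFeature | Tensor, T: int) -> Tensor:
    """Trilinear interpolation of an axis feature onto ``(T, 4, 4)``.

    The T-axis feature already has that shape and passes through unchanged.
    """
    if isinstance(feature, AxisFeature):
        if feature.axis.name == "T":
            return feature.tensor
        x = feature.tensor
    else:
        x = as_tensor(feature)
    if x.ndim != 5:
        raise ValueError("axis feature must be 5-D")
    targets = (T, 4, 4)
    for k, tgt in enumerate(targets):
        ax = 2 + k
        if x.shape[ax] != tgt:
            x = _apply_matrix_axis(x, _interp_matrix(x.shape[ax], tgt), ax)
    return x


def _adaptive_pool_matrix(s: int, out: int) -> np.ndarray:
    """Averaging matrix for adaptive 1-D average pooling (s -> out bins)."""
    w = np.zeros((s, out))
    edges = (np.arange(out + 1) * s) // out
    for b in range(out):
        lo, hi = edges[b], max(edges[b] + 1, edges[b + 1])
        w[lo:hi, b] = 1.0 / (hi - lo)
    return w


# ---- learnable blocks ---------------------------------------------------


class FeatureBlock2D(nn.Module):
    """Two stride-2 3x3 convolutions (padding 1) with ReLU; C preserved."""

    def __init__(self, channels: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, rng, stride=2, padding=1)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng, stride=2, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("spatial dims must be divisible by 4")
        return self.conv2(self.conv1(x).relu()).relu()


class WindowAttention(nn.Module):
    """Pre-LN multi-head self-attention over a token axis."""

    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        self.heads = heads
        self.norm = nn.LayerNorm(dim)
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        """tokens: (batch, n_tokens, dim); returns the residual branch output."""
        b, n, d = tokens.shape
        hd = d // self.heads
        x = self.norm(tokens)
        q = self.q(x).reshape(b, n, self.heads, hd).transpose(0, 2, 1, 3)
        k = self.k(x).reshape(b, n, self.heads, hd).transpose(0, 2, 1, 3)
        v = self.v(x).reshape(b, n, self.heads, hd).transpose(0, 2, 1, 3)
        att = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(hd))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)


class MaxViTLayer(nn.Module):
    """MaxViT-style unit on a (B, C, D1, S) map.

    A residual convolutional unit (the MBConv role), windowed *block*
    attention inside non-overlapping ``p1 x p2`` tiles, then *grid* attention
    across tiles — local and global mixing of the spatio-temporal map.  Maps
    whose sides are not multiples of the window are zero-padded for the
    attention and cropped back.
    """

    def __init__(self, channels: int, heads: int, window: tuple[int, int], rng):
        super().__init__()
        self.window = window
        self.conv1 = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.block_attn = WindowAttention(channels, heads, rng)
        self.grid_attn = WindowAttention(channels, heads, rng)

    def init_identity(self) -> None:
        """Zero the residual branches so the layer is exactly the identity."""
        self.conv2.weight.data[:] = 0.0
        self.conv2.bias.data[:] = 0.0
        for attn in (self.block_attn, self.grid_attn):
            attn.proj.weight.data[:] = 0.0
            attn.proj.bias.data[:] = 0.0

    def _windowed(self, x: Tensor, attn: WindowAttention, grid: bool) -> Tensor:
        b, c, d1, s = x.shape
        p1, p2 = self.window
        pad1 = (-d1) % p1
        pad2 = (-s) % p2
        if pad1 or pad2:
            x = x.pad(((0, 0), (0, 0), (0, pad1), (0, pad2)))
        n1, n2 = x.shape[2] // p1, x.shape[3] // p2
        y = x.reshape(b, c, n1, p1, n2, p2)
        if grid:
            # tokens = tile positions (n1, n2), one attention per offset (p1, p2)
            y = y.transpose(0, 3, 5, 2, 4, 1)        # (B, p1, p2, n1, n2, C)
            tok = y.reshape(b * p1 * p2, n1 * n2, c)
            tok = attn(tok)
            y = tok.reshape(b, p1, p2, n1, n2, c).transpose(0, 5, 3, 1, 4, 2)
        else:
            # tokens = positions inside a tile, one attention per tile
            y = y.transpose(0, 2, 4, 3, 5, 1)        # (B, n1, n2, p1, p2, C)
            tok = y.reshape(b * n1 * n2, p1 * p2, c)
            tok = attn(tok)
            y = tok.reshape(b, n1, n2, p1, p2, c).transpose(0, 5, 1, 3, 2, 4)
        y = y.reshape(b, c, n1 * p1, n2 * p2)
        if pad1 or pad2:
            y = y[:, :, :d1, :s]
        return y

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.conv2(self.conv1(x).relu())
        x = x + self._windowed(x, self.block_attn, grid=False)
        x = x + self._windowed(x, self.grid_attn, grid=True)
        return x


class SpatialAttention(nn.Module):
    """CBAM-style gate: channel max+mean pool -> 2-layer conv -> sigmoid mask."""

    def __init__(self, rng, hidden: int = 4):
        super().__init__()
        self.conv1 = nn.Conv2d(2, hidden, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(hidden, 1, 3, rng, padding=1)
        self.bypass = False  # diagnostics: skip gating entirely

    def mask(self, x: Tensor) -> Tensor:
        pooled = nn.cat([x.max(axis=1, keepdims=True), x.mean(axis=1, keepdims=True)],
                        axis=1)
        return self.conv2(self.conv1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if self.bypass:
            return x
        return x * self.mask(x)


class STFeatureBlock(nn.Module):
    """MaxViT-style layer(s) followed by the spatial-attention gate."""

    def __init__(self, channels: int, heads: int, window: tuple[int, int],
                 depth: int, rng):
        super().__init__()
        self.layers = [MaxViTLayer(channels, heads, window, rng) for _ in range(depth)]
        self.gate = SpatialAttention(rng)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return self.gate(x)


class AxisExtractor(nn.Module):
    """One axis stream: project -> 2-D features -> map -> MaxViT -> tail.

    The tail pools the map columns to 16 adaptive bins for every axis; the
    T-axis feature is reshaped to ``(B, C, T, 4, 4)`` while H/W features are
    reshaped to ``(B, C, D1, 4, 4)`` and transposed to ``(B, C, 4, D1, 4)``,
    ready for interpolation onto the T-axis shape.
    """

    def __init__(self, axis: AxisTag, config: ModelConfig, rng):
        super().__init__()
        self.axis = axis
        self.config = config
        c = config.channels
        self.embed = None if c == 3 else nn.Conv2d(3, c, 1, rng)
        self.block2d = FeatureBlock2D(c, rng)
        self.st_block = STFeatureBlock(c, config.attn_heads, config.attn_window,
                                       config.maxvit_depth, rng)

    def forward(self, batch) -> AxisFeature:
        x = as_tensor(batch)
        b = x.shape[0]
        y = axis_project(x, self.axis)
        if self.embed is not None:
            y = self.embed(y)
        y = self.block2d(y)
        y = st_translate(y, b)
        y = self.st_block(y)
        s = y.shape[-1]
        if s != 16:
            y = apply_matrix_last(y, _adaptive_pool_matrix(s, 16))
        d1 = y.shape[2]
        y = y.reshape(b, self.config.channels, d1, 4, 4)
        if self.axis.name != "T":
            y = y.transpose(0, 1, 3, 2, 4)   # (B, C, 4, D1, 4)
        return AxisFeature(tensor=y, axis=self.axis)


def mix_features(e_t, e_h, e_w, case: int) -> MixedFeature:
    """Combine the three (interpolated) axis features; the ten mixer cases.

    All inputs must already be ``(B, C, T, 4, 4)`` (H/W via
    :func:`interp_to_T`).  ``*`` below is elementwise, ``@`` the batched 4x4
    matrix product over the trailing dims:

    1. ``(e_w @ e_h) * e_t + e_t``    6. ``(e_w + e_h) * e_t``
    2. ``e_t``                        7. ``e_w * e_t``
    3. ``e_w * e_t + e_t``            8. ``e_h * e_t``
    4. ``e_h * e_t + e_t``            9. ``e_w``
    5. ``(e_w + e_h) * e_t + e_t``   10. ``e_h``
    """
    e_t, e_h, e_w = (x.tensor if isinstance(x, AxisFeature) else as_tensor(x)
                     for x in (e_t, e_h, e_w))
    if case == 1:
        out = (e_w @ e_h) * e_t + e_t
    elif case == 2:
        out = e_t
    elif case == 3:
        out = e_w * e_t + e_t
    elif case == 4:
        out = e_h * e_t + e_t
    elif case == 5:
        out = (e_w + e_h) * e_t + e_t
    elif case == 6:
        out = (e_w + e_h) * e_t
    elif case == 7:
        out = e_w * e_t
    elif case == 8:
        out = e_h * e_t
    elif case == 9:
        out = e_w
    elif case == 10:
        out = e_h
    else:
        raise ValueError("mixer case must be in 1..10")
    return MixedFeature(tensor=out)


class PPGDecoder(nn.Module):
    """(B, C, T, 4, 4) attentive feature -> (B, T) signal.

    Reshape to a (T, 16) map, a 3x3 convolution mapping C channels to T,
    spatial averaging over the 16 columns, a residual pair of 1-D
    convolutions, and a final T-to-1 convolution.
    """

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        t = config.T
        hidden = config.decoder_hidden or t
        self.conv2d = nn.Conv2d(config.channels, t, 3, rng, padding=1)
        self.res1 = nn.Conv1d(t, hidden, 3, rng, padding=1)
        self.res2 = nn.Conv1d(hidden, t, 3, rng, padding=1)
        self.head = nn.Conv1d(t, 1, 3, rng, padding=1)

    def forward(self, mixed) -> Tensor:
        x = mixed.tensor if isinstance(mixed, MixedFeature) else as_tensor(mixed)
        b, c, t, _, _ = x.shape
        x = x.reshape(b, c, t, 16)
        x = self.conv2d(x)                   # (B, T, T, 16)
        x = x.mean(axis=-1)                  # (B, T, T)
        x = x + self.res2(self.res1(x).relu())
        x = self.head(x)                     # (B, 1, T)
        return x.reshape(b, t)


class AxisProjectionNet(nn.Module):
    """The full network: three axis extractors, a feature mixer, a decoder."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        self.extractor_t = AxisExtractor(AxisTag("T"), self.config, rng)
        self.extractor_h = AxisExtractor(AxisTag("H"), self.config, rng)
        self.extractor_w = AxisExtractor(AxisTag("W"), self.config, rng)
        self.decoder = PPGDecoder(self.config, rng)

    def extract_features(self, batch) -> dict[str, AxisFeature]:
        x = as_tensor(batch)
        b, c, t, h, w = x.shape
        if c != 3 or t != self.config.T or h != self.config.size or w != self.config.size:
            raise ValueError(
                f"input {x.shape} incompatible with config "
                f"(3, {self.config.T}, {self.config.size}, {self.config.size})")
        x = x.astype(nn.DEFAULT_DTYPE)
        return {"T": self.extractor_t(x), "H": self.extractor_h(x),
                "W": self.extractor_w(x)}

    def forward(self, batch) -> Tensor:
        feats = self.extract_features(batch)
        t = self.config.T
        mixed = mix_features(interp_to_T(feats["T"], t), interp_to_T(feats["H"], t),
                             interp_to_T(feats["W"], t), self.config.mixer_case)
        return self.decoder(mixed)

    def predict(self, batch) -> np.ndarray:
        """Inference without graph construction; returns a numpy (B, T) array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(batch).numpy()
        finally:
            self.train(was_training)
        return out

    # ---- persistence ---------------------------------------------------

    CHECKPOINT_SCHEMA = 1

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = {"schema": self.CHECKPOINT_SCHEMA, "config": self.config.to_dict()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AxisProjectionNet":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig.from_dict(sidecar["config"]))
        weights = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        model.load_state_dict({k: weights[k] for k in weights.files})
        return model


def count_parameters(config: ModelConfig | None = None) -> tuple[int, int]:
    """Trainable parameter count and fp32 storage bytes for a configuration."""
    model = AxisProjectionNet(config or ModelConfig())
    n = model.n_parameters()
    return n, 4 * n
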
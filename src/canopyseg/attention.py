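"""Feature-map attention: the channel-axial-spatial (CAS) module and baselines.

CAS enhances a backbone feature map in three sequential steps:

1. **Channel gating** — global average- and max-pooled channel descriptors
   pass through a shared bottleneck MLP; the sigmoid of their sum scales
   each channel (the CBAM channel gate).
2. **Axial enhancement** — single-head scaled dot-product self-attention
   applied independently along every row and every column of the map
   (shared query/key/value channel projections, no positional encoding);
   the row-attended and column-attended maps are summed.
3. **Spatial gating** — the channel-wise mean and max maps are stacked and
   convolved with one k x k filter (default 7); the sigmoid output gates
   every pixel.

All transforms preserve the (C, H, W) shape, and every gate value lies
strictly inside (0, 1).  ECA (a 1-D convolution over the pooled channel
vector), CBAM (channel + spatial without the axial step) and the bare
axial step are available as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Parameter, Tensor, concat, conv2d

__all__ = [
    "AttentionSpec",
    "ChannelAttention",
    "AxialEnhance",
    "SpatialAttention",
    "CAS",
    "ECA",
    "CBAM",
    "build_attention",
    "channel_attention",
    "axial_enhance",
    "spatial_attention",
    "cas_forward",
    "eca_forward",
]

ATTENTION_KINDS = ("none", "cas", "eca", "cbam", "axial")


@dataclass
class AttentionSpec:
    kind: str = "none"
    reduction_ratio: int = 16
    spatial_kernel: int = 7
    eca_kernel: int = 3

    def __post_init__(self):
        if self.kind not in ATTENTION_KINDS:
            raise ValueError(f"unknown attention kind {self.kind!r}; supported: {ATTENTION_KINDS}")
        if self.reduction_ratio < 1:
            raise ValueError(f"reduction_ratio must be >= 1, got {self.reduction_ratio}")
        if self.spatial_kernel % 2 == 0:
            raise ValueError(f"spatial_kernel must be odd so padding preserves H, W; got {self.spatial_kernel}")
        if self.eca_kernel % 2 == 0:
            raise ValueError(f"eca_kernel must be odd; got {self.eca_kernel}")


def _check_finite(x: Tensor) -> None:
    if not np.isfinite(x.data).all():
        raise ValueError("attention input contains non-finite values")


class ChannelAttention(nn.Module):
    """Per-channel sigmoid gate from pooled descriptors through a shared MLP."""

    def __init__(self, channels: int, reduction_ratio: int = 16):
        super().__init__()
        if reduction_ratio > channels:
            raise ValueError(
                f"reduction_ratio {reduction_ratio} exceeds channel count {channels}; "
                "the MLP bottleneck would be empty"
            )
        hidden = channels // reduction_ratio
        self.fc1 = nn.Linear(channels, hidden, bias=False)
        self.fc2 = nn.Linear(hidden, channels, bias=False)

    def gate(self, x: Tensor) -> Tensor:
        N, C = x.shape[0], x.shape[1]
        avg = F.global_avg_pool(x, keepdims=False).reshape(N, C)
        mx = F.global_max_pool(x, keepdims=False)
        pre = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return pre.sigmoid().reshape(N, C, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class AxialEnhance(nn.Module):
    """Row + column single-head self-attention with shared channel projections.

    For each row (sequence length W) and each column (sequence length H),
    tokens are the C-dimensional pixel vectors; attention weights are
    softmax(QK^T / sqrt(C)).  The two attended maps are summed.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.wq = nn.Linear(channels, channels, bias=False)
        self.wk = nn.Linear(channels, channels, bias=False)
        self.wv = nn.Linear(channels, channels, bias=False)

    def _attend(self, seq: Tensor) -> Tensor:
        # seq: (B, L, C)
        q, k, v = self.wq(seq), self.wk(seq), self.wv(seq)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.channels))
        return scores.softmax(axis=-1) @ v

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        rows = x.transpose(0, 2, 3, 1).reshape(N * H, W, C)
        rf = self._attend(rows).reshape(N, H, W, C).transpose(0, 3, 1, 2)
        cols = x.transpose(0, 3, 2, 1).reshape(N * W, H, C)
        cf = self._attend(cols).reshape(N, W, H, C).transpose(0, 3, 2, 1)
        return rf + cf


class SpatialAttention(nn.Module):
    """Per-pixel sigmoid gate from the stacked channel-mean and channel-max maps."""

    def __init__(self, kernel: int = 7):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"spatial attention kernel must be odd, got {kernel}")
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2, bias=True)

    def gate(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class CAS(nn.Module):
    """Channel -> axial -> spatial enhancement, in that order."""

    def __init__(self, channels: int, spec: AttentionSpec | None = None):
        super().__init__()
        spec = spec or AttentionSpec(kind="cas")
        self.channel = ChannelAttention(channels, spec.reduction_ratio)
        self.axial = AxialEnhance(channels)
        self.spatial = SpatialAttention(spec.spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.axial(self.channel(x)))


class CBAM(nn.Module):
    """Channel then spatial gating (the CAS module without the axial step)."""

    def __init__(self, channels: int, spec: AttentionSpec | None = None):
        super().__init__()
        spec = spec or AttentionSpec(kind="cbam")
        self.channel = ChannelAttention(channels, spec.reduction_ratio)
        self.spatial = SpatialAttention(spec.spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.spatial(self.channel(x))


class ECA(nn.Module):
    """Efficient channel attention: 1-D conv over the pooled channel vector."""

    def __init__(self, channels: int, kernel: int = 3):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"ECA kernel must be odd, got {kernel}")
        self.kernel = kernel
        self.weight = Parameter(np.full((1, 1, kernel, 1), 1.0 / kernel, dtype=np.float32))

    def gate(self, x: Tensor) -> Tensor:
        N, C = x.shape[0], x.shape[1]
        avg = F.global_avg_pool(x, keepdims=False).reshape(N, 1, C, 1)
        pre = conv2d(avg, self.weight, padding=(self.kernel // 2, 0))
        return pre.sigmoid().reshape(N, C, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


def build_attention(channels: int, spec: AttentionSpec) -> nn.Module:
    """Instantiate the attention module named by ``spec.kind`` (or Identity)."""
    if spec.kind == "none":
        return nn.Identity()
    if spec.kind == "cas":
        return CAS(channels, spec)
    if spec.kind == "cbam":
        return CBAM(channels, spec)
    if spec.kind == "axial":
        return AxialEnhance(channels)
    if spec.kind == "eca":
        return ECA(channels, spec.eca_kernel)
    raise ValueError(f"unknown attention kind {spec.kind!r}")


# -- array-level convenience wrappers ----------------------------------------
# Each accepts a (C, H, W) feature map array, builds (or reuses) the module,
# and returns the transformed array.

def _apply(module: nn.Module, fmap: np.ndarray) -> np.ndarray:
    t = Tensor(np.asarray(fmap, dtype=np.float32)[None])
    _check_finite(t)
    out = module(t)
    return out.data[0]


def channel_attention(fmap: np.ndarray, spec: AttentionSpec, module: ChannelAttention | None = None) -> np.ndarray:
    module = module or ChannelAttention(fmap.shape[0], spec.reduction_ratio)
    return _apply(module, fmap)


def axial_enhance(fmap: np.ndarray, module: AxialEnhance | None = None) -> np.ndarray:
    module = module or AxialEnhance(fmap.shape[0])
    return _apply(module, fmap)


def spatial_attention(fmap: np.ndarray, spec: AttentionSpec, module: SpatialAttention | None = None) -> np.ndarray:
    module = module or SpatialAttention(spec.spatial_kernel)
    return _apply(module, fmap)


def cas_forward(fmap: np.ndarray, spec: AttentionSpec, module: CAS | None = None) -> np.ndarray:
    module = module or CAS(fmap.shape[0], spec)
    return _apply(module, fmap)


def eca_forward(fmap: np.ndarray, spec: AttentionSpec, module: ECA | None = None) -> np.ndarray:
    module = module or ECA(fmap.shape[0], spec.eca_kernel)
    return _apply(module, fmap)
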
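"""Spatial operators (pooling, bilinear resampling) for NCHW tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "max_pool2d",
    "adaptive_avg_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "interpolate_bilinear",
]


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    N, C, H, W = x.shape
    Ho = (H + 2 * padding - kernel) // stride + 1
    Wo = (W + 2 * padding - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf) if padding else x.data
    h_span = (Ho - 1) * stride + 1
    w_span = (Wo - 1) * stride + 1
    windows = np.stack(
        [
            xp[:, :, i : i + h_span : stride, j : j + w_span : stride]
            for i in range(kernel)
            for j in range(kernel)
        ]
    )  # (k*k, N, C, Ho, Wo)
    idx = windows.argmax(axis=0)
    out_data = np.take_along_axis(windows, idx[None], axis=0)[0]

    def backward(g):
        dxp = np.zeros_like(xp)
        for pos in range(kernel * kernel):
            i, j = divmod(pos, kernel)
            mask = idx == pos
            dxp[:, :, i : i + h_span : stride, j : j + w_span : stride] += g * mask
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    return Tensor._op(out_data, (x,), backward)


def _bins(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * n_in / n_out)), int(np.ceil((i + 1) * n_in / n_out))) for i in range(n_out)]


def adaptive_avg_pool2d(x: Tensor, out_size: int) -> Tensor:
    """Average-pool to ``out_size`` x ``out_size`` with adaptive bin edges."""
    N, C, H, W = x.shape
    if H < out_size or W < out_size:
        raise ValueError(f"adaptive pool target {out_size} exceeds input extent {(H, W)}")
    hb, wb = _bins(H, out_size), _bins(W, out_size)
    out_data = np.empty((N, C, out_size, out_size), dtype=x.data.dtype)
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def backward(g):
        dx = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                dx[:, :, h0:h1, w0:w1] += g[:, :, i : i + 1, j : j + 1] / ((h1 - h0) * (w1 - w0))
        x._accum(dx)

    return Tensor._op(out_data, (x,), backward)


def global_avg_pool(x: Tensor, keepdims: bool = True) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=keepdims)


def global_max_pool(x: Tensor, keepdims: bool = True) -> Tensor:
    N, C, H, W = x.shape
    flat = x.reshape(N, C, H * W).max(axis=2)
    return flat.reshape(N, C, 1, 1) if keepdims else flat


def _linear_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic (n_out, n_in) matrix for half-pixel bilinear resampling."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    M[np.arange(n_out), lo] += 1.0 - frac
    M[np.arange(n_out), hi] += frac
    return M


def interpolate_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize (align_corners=False) expressed as two separable matmuls."""
    N, C, H, W = x.shape
    Ho, Wo = size
    if (Ho, Wo) == (H, W):
        return x
    dt = np.float64 if x.data.dtype == np.float64 else np.float32
    Mh = _linear_matrix(H, Ho, dt)
    Mw = _linear_matrix(W, Wo, dt)
    out_data = np.einsum("oh,nchw,pw->ncop", Mh, x.data, Mw, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", Mh, g, Mw, optimize=True))

    return Tensor._op(out_data, (x,), backward)
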
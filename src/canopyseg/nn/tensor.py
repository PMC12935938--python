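"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based tensor core sized for CPU segmentation networks: it
supports exactly the operations the package's models need (grouped/dilated
convolution, pooling, bilinear resampling, softmax/attention arithmetic,
batch-norm statistics) and nothing more.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv2d", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        tracked = tuple(p for p in prev if p.requires_grad or p._prev)
        if tracked:
            out._prev = tracked
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={'yes' if self.grad is not None else 'no'})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            da = np.matmul(g, np.swapaxes(other.data, -1, -2))
            db = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(da, self.shape))
            other._accum(_unbroadcast(db, other.shape))

        return Tensor._op(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._op(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return Tensor._op(np.transpose(self.data, axes), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).astype(self.data.dtype))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).astype(self.data.dtype))

        return Tensor._op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            dx = np.zeros_like(self.data)
            np.put_along_axis(dx, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(dx)

        return Tensor._op(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._op(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._op(out_data, (self,), backward)

    def hardsigmoid(self):
        out_data = np.clip(self.data / 6.0 + 0.5, 0.0, 1.0)
        mask = (self.data > -3.0) & (self.data < 3.0)

        def backward(g):
            self._accum(g * mask / 6.0)

        return Tensor._op(out_data.astype(self.data.dtype), (self,), backward)

    def hardswish(self):
        hs = np.clip(self.data / 6.0 + 0.5, 0.0, 1.0)
        out_data = self.data * hs
        deriv = np.where(self.data <= -3.0, 0.0, np.where(self.data >= 3.0, 1.0, (2.0 * self.data + 3.0) / 6.0))

        def backward(g):
            self._accum(g * deriv.astype(self.data.dtype))

        return Tensor._op(out_data.astype(self.data.dtype), (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._op(out_data, (self,), backward)

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        # interior nodes get fresh grads each sweep; leaves accumulate
        for node in topo:
            if node._prev:
                node.grad = None
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)
            if node._prev and not node.requires_grad:
                node.grad = None  # free interior grad memory eagerly


class Parameter(Tensor):
    """A leaf tensor optimised during training."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._op(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int | tuple[int, int] = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Grouped, dilated 2-D cross-correlation, NCHW layout.

    Implemented as a sum of ``k*k`` shifted channel contractions so no im2col
    buffer is materialised; each term is a single einsum (BLAS matmul).
    """
    N, Cin, H, W = x.shape
    Cout, cpg, kh, kw = w.shape
    if Cin != cpg * groups:
        raise ValueError(f"input channels {Cin} incompatible with weight {w.shape} and groups {groups}")
    dpg = Cout // groups
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    Ho = (H + 2 * ph - dilation * (kh - 1) - 1) // stride + 1
    Wo = (W + 2 * pw - dilation * (kw - 1) - 1) // stride + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"conv2d output would be empty for input {x.shape} kernel {w.shape}")

    padding = ph or pw
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if padding else x.data
    xg = xp.reshape(N, groups, cpg, xp.shape[2], xp.shape[3])
    wg = w.data.reshape(groups, dpg, cpg, kh, kw)
    out = np.zeros((N, groups, dpg, Ho, Wo), dtype=np.result_type(x.data, w.data))
    h_span = (Ho - 1) * stride + 1
    w_span = (Wo - 1) * stride + 1
    for i in range(kh):
        for j in range(kw):
            xs = xg[:, :, :, i * dilation : i * dilation + h_span : stride, j * dilation : j * dilation + w_span : stride]
            out += np.einsum("ngchw,gdc->ngdhw", xs, wg[:, :, :, i, j], optimize=True)
    out_data = out.reshape(N, Cout, Ho, Wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, Cout, 1, 1)

    prev = (x, w) if b is None else (x, w, b)

    def backward(g):
        gg = g.reshape(N, groups, dpg, Ho, Wo)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        dw = np.zeros_like(wg)
        dxp = np.zeros_like(xp)
        dxg = dxp.reshape(N, groups, cpg, xp.shape[2], xp.shape[3])
        for i in range(kh):
            for j in range(kw):
                hsl = slice(i * dilation, i * dilation + h_span, stride)
                wsl = slice(j * dilation, j * dilation + w_span, stride)
                xs = xg[:, :, :, hsl, wsl]
                dw[:, :, :, i, j] = np.einsum("ngchw,ngdhw->gdc", xs, gg, optimize=True)
                dxg[:, :, :, hsl, wsl] += np.einsum("ngdhw,gdc->ngchw", gg, wg[:, :, :, i, j], optimize=True)
        w._accum(dw.reshape(w.shape))
        if padding:
            x._accum(dxp[:, :, ph : dxp.shape[2] - ph, pw : dxp.shape[3] - pw])
        else:
            x._accum(dxp)

    return Tensor._op(out_data, prev, backward)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixel-wise cross-entropy.

    ``logits``: (N, C, ...) raw scores; ``target``: integer array (N, ...).
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    tgt = np.asarray(target)
    picked = np.take_along_axis(z, np.expand_dims(tgt, 1), axis=1)
    losses = (lse - picked)[:, 0]
    count = losses.size
    out_data = np.asarray(losses.mean(), dtype=z.dtype)

    def backward(g):
        p = np.exp(z - lse)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, np.expand_dims(tgt, 1), 1.0, axis=1)
        logits._accum(g * (p - onehot) / count)

    return Tensor._op(out_data, (logits,), backward)
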
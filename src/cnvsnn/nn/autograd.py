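"""A small reverse-mode automatic differentiation engine over numpy arrays.

Supports exactly the operations the classifiers need: broadcasting
arithmetic, matmul, ReLU/sigmoid/exp/log, reductions, reshape, 2-D
convolution (im2col + BLAS matmul, with a transposed-convolution backward),
max pooling with region clipping, and the hard/smoothed spike
nonlinearities whose backward pass is the surrogate derivative
``1 / (k·|u| + 1)²`` (input already centred on the firing threshold).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat0",
    "conv2d",
    "maxpool2d",
    "spike",
    "smooth_spike",
    "surrogate_derivative",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def narrow0(self, start: int, stop: int):
        """Slice along axis 0 (gradient scatters back into place)."""
        shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                full = np.zeros(shape)
                full[start:stop] = g
                self._accum(full)

        return Tensor._make(self.data[start:stop], (self,), backward)


def concat0(tensors: list["Tensor"]) -> "Tensor":
    """Concatenate along axis 0; the backward pass splits the gradient."""
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accum(g[a:b])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=0), tuple(tensors), backward
    )


# ---------------------------------------------------------------------------
# spike nonlinearities


def surrogate_derivative(u_centred: np.ndarray, k: float) -> np.ndarray:
    """Backward-pass stand-in for the Heaviside derivative:
    ``1 / (k·|u| + 1)²`` with ``u`` already centred on the threshold."""
    return 1.0 / (k * np.abs(u_centred) + 1.0) ** 2


def spike(u: Tensor, k: float) -> Tensor:
    """Hard threshold at 0 (fires on equality) with surrogate backward."""
    if np.isnan(u.data).any():
        raise FloatingPointError("NaN membrane potential")
    out_data = (u.data >= 0.0).astype(np.float64)

    def backward(g):
        if u.requires_grad:
            u._accum(g * surrogate_derivative(u.data, k))

    return Tensor._make(out_data, (u,), backward)


def smooth_spike(u: Tensor, k: float) -> Tensor:
    """Smoothed spike ``u / (1 + k|u|)``; its exact derivative equals the
    surrogate, so finite differences of this forward match the backward."""
    out_data = u.data / (1.0 + k * np.abs(u.data))

    def backward(g):
        if u.requires_grad:
            u._accum(g * surrogate_derivative(u.data, k))

    return Tensor._make(out_data, (u,), backward)


# ---------------------------------------------------------------------------
# convolution and pooling


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D valid cross-correlation, stride 1, no padding.

    ``x``: (B, C, H, W); ``w``: (F, C, kh, kw); ``b``: (F,).
    Forward and both backward passes are expressed as matmuls over an
    im2col layout.
    """
    B, C, H, W = x.data.shape
    F, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"input has {C} channels but kernel expects {Cw}")
    if H < kh or W < kw:
        raise ValueError(f"input {H}×{W} smaller than kernel {kh}×{kw}")
    Ho, Wo = H - kh + 1, W - kw + 1

    win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))  # (B,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, -1)
    out = cols @ wmat.T  # (B·L, F): one large GEMM
    if b is not None:
        out = out + b.data
    out = out.reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, F)
        if w.requires_grad:
            w._accum((gl.T @ cols).reshape(F, C, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(gl.sum(axis=0))
        if x.requires_grad:
            # transposed convolution, accumulated per kernel offset: cheaper
            # than an im2col of the padded gradient for small feature maps
            gxt = np.zeros((B, H, W, C))
            for p in range(kh):
                for q in range(kw):
                    contrib = (gl @ w.data[:, :, p, q]).reshape(B, Ho, Wo, C)
                    gxt[:, p : p + Ho, q : q + Wo, :] += contrib
            x._accum(np.ascontiguousarray(gxt.transpose(0, 3, 1, 2)))

    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, size: int = 2, stride: int | None = None) -> Tensor:
    """Max pooling with square regions, clipped to the available extent.

    A ``size``×``size`` pool on a map with fewer rows (or columns) than
    ``size`` pools only the dimension that has room — this is what lets the
    fixed two-layer architecture run on very few input channels.
    """
    if stride is not None and stride != size:
        raise NotImplementedError("only stride == pool size is supported")
    B, C, H, W = x.data.shape
    ph, pw = min(size, H), min(size, W)
    Ho, Wo = H // ph, W // pw
    crop = x.data[:, :, : Ho * ph, : Wo * pw]
    blocks = crop.reshape(B, C, Ho, ph, Wo, pw).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(blocks).reshape(B, C, Ho, Wo, ph * pw)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gcrop = (
            gflat.reshape(B, C, Ho, Wo, ph, pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, Ho * ph, Wo * pw)
        )
        gx = np.zeros_like(x.data)
        gx[:, :, : Ho * ph, : Wo * pw] = gcrop
        x._accum(gx)

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# losses


def bce_with_logits(z: Tensor, y: np.ndarray, sample_weight: np.ndarray | None = None) -> Tensor:
    """Numerically stable weighted binary cross entropy on logits.

    ``z``: (B,) or (B, 1) logits; ``y``: (B,) binary targets.  Gradient is
    ``w·(σ(z) − y)/B`` — exact, no clipping of probabilities needed.
    """
    zf = z.data.reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    s = 1.0 / (1.0 + np.exp(-np.clip(zf, -500, 500)))
    # softplus(z) - y*z, stable form
    loss = np.maximum(zf, 0) - zf * y + np.log1p(np.exp(-np.abs(zf)))
    val = np.array((w * loss).mean())

    def backward(g):
        if z.requires_grad:
            gz = (g * w * (s - y) / y.size).reshape(z.data.shape)
            z._accum(gz)

    return Tensor._make(val, (z,), backward)
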
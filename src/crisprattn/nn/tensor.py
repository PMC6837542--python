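"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every upstream tensor created with ``requires_grad=True``. The op set is
deliberately small — exactly what the sequence models in this package need:
broadcast arithmetic, (batched) matmul, pointwise nonlinearities, reductions,
reshapes, slicing, concatenation, a numerically stable log-softmax, embedding
lookup, 2-d valid convolution via im2col, and max pooling.

All arrays are float64; gradients are checked numerically in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "embedding", "conv2d", "max_pool2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float64, copy=True)
        else:
            self.grad += grad

    # -- autograd driver ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from LSTM loops can be deep
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
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data**p

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        a, b = self.data, other.data
        if a.ndim > 2 and b.ndim == 2:
            # stack the leading axes into one big GEMM (the Linear-layer case)
            k = a.shape[-1]
            out_data = (a.reshape(-1, k) @ b).reshape(*a.shape[:-1], b.shape[1])

            def bwd(g):
                g2 = g.reshape(-1, b.shape[1])
                if self.requires_grad:
                    self._accumulate((g2 @ b.T).reshape(a.shape))
                if other.requires_grad:
                    other._accumulate(a.reshape(-1, k).T @ g2)

            return Tensor(out_data, _parents=(self, other), _backward=bwd)

        out_data = np.matmul(a, b)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(b, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bwd)

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- reductions / shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bwd)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    # -- softmax family -----------------------------------------------------
    def log_softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bwd(g):
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor(out_data, _parents=(self,), _backward=bwd)

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, _parents=tuple(tensors), _backward=bwd)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with sparse gradient accumulation."""
    idx = np.asarray(indices)
    out_data = weight.data[idx]

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        weight._accumulate(full)

    return Tensor(out_data, _parents=(weight,), _backward=bwd)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H', W', C*kh*kw) patch matrix, valid padding."""
    b, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, shape=(b, c, oh, ow, kh, kw), strides=(s0, s1, s2, s3, s2, s3)
    )
    # -> (B, OH, OW, C, KH, KW) -> flatten patch dims
    return np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b, oh, ow, c * kh * kw
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Valid 2-d cross-correlation.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, KH, KW); ``bias``: (C_out,).
    Returns (B, C_out, H-KH+1, W-KW+1).
    """
    b, c_in, h, w = x.shape
    c_out, _, kh, kw = weight.shape
    oh, ow = h - kh + 1, w - kw + 1
    cols = _im2col(x.data, kh, kw)  # (B, OH, OW, C*KH*KW)
    wmat = weight.data.reshape(c_out, -1)  # (C_out, C*KH*KW)
    out_data = cols.reshape(-1, c_in * kh * kw) @ wmat.T + bias.data
    out_data = out_data.reshape(b, oh, ow, c_out).transpose(0, 3, 1, 2)

    def bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, c_out)
        if weight.requires_grad:
            gw = gmat.T @ cols.reshape(-1, c_in * kh * kw)
            weight._accumulate(gw.reshape(weight.shape))
        if bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(b, oh, ow, c_in, kh, kw)
            gx = np.zeros_like(x.data)
            for i in range(kh):  # col2im scatter; kernels are tiny (3x3)
                for j in range(kw):
                    gx[:, :, i : i + oh, j : j + ow] += gcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            x._accumulate(gx)

    return Tensor(out_data, _parents=(x, weight, bias), _backward=bwd)


def max_pool2d(x: Tensor, kh: int, kw: int) -> Tensor:
    """Non-overlapping max pooling with floor truncation of the remainder."""
    b, c, h, w = x.shape
    oh, ow = h // kh, w // kw
    trimmed = x.data[:, :, : oh * kh, : ow * kw]
    windows = trimmed.reshape(b, c, oh, kh, ow, kw).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(b, c, oh, ow, kh * kw)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gwin = gflat.reshape(b, c, oh, ow, kh, kw).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, : oh * kh, : ow * kw] = gwin.reshape(b, c, oh * kh, ow * kw)
        x._accumulate(gx)

    return Tensor(out_data, _parents=(x,), _backward=bwd)
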
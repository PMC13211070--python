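"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine: just the operations the ECG models need
(elementwise arithmetic, matmul, reductions, slicing, grouped 1-D
convolution) with gradients verified against finite differences in the test
suite.  Arrays are float64 by default (switchable to float32 for faster
desk-scale training); all shapes follow numpy broadcasting rules.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True
_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the dtype newly created tensors use (float64 default; float32
    roughly halves training time at desk scale)."""
    global _DEFAULT_DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = np.dtype(dtype)


def get_default_dtype():
    return _DEFAULT_DTYPE


@contextlib.contextmanager
def default_dtype(dtype):
    prev = get_default_dtype()
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._grad_owned = False

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        requires = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=requires)
        if requires:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autograd -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accumulate(self, grad: np.ndarray) -> None:
        # copy-on-write: keep a reference on first arrival, materialize an
        # owned array only if a second contribution shows up
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)
        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                a = self.data
                if a.ndim == 1:
                    gb = np.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._result(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        return self._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return self._result(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * np.sign(self.data))
        return self._result(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._result(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return self._result(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            expanded = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == expanded).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True)  # ties share gradient
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)

        return self._result(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return self._result(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))
        return self._result(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros(self.shape)
                np.add.at(full, idx, g)
                self._accumulate(full)
        return self._result(self.data[idx], (self,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(g[tuple(sl)])

    return Tensor._result(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtract a detached max for numerical stability; gradient is unchanged
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def fused_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               axes: tuple[int, ...], eps: float,
               param_shape: tuple[int, ...] | None = None,
               stats: tuple[np.ndarray, np.ndarray] | None = None,
               stats_from_x: bool = True) -> Tensor:
    """Normalization with affine parameters as one primitive.

    Computes gamma * (x - mean) / sqrt(var + eps) + beta with mean/var taken
    over `axes` (layer norm: last axis; batch norm: batch and time).  The
    closed-form backward avoids building the ~10-node graph the composed
    version would create.  `param_shape` broadcasts gamma/beta against x
    (e.g. (1, C, 1)); `stats` supplies externally computed (mean, var);
    `stats_from_x=False` marks stats as constants (batch-norm eval mode),
    which drops the mean/variance terms from the input gradient.
    """
    mu, var = stats if stats is not None else (
        x.data.mean(axis=axes, keepdims=True),
        x.data.var(axis=axes, keepdims=True))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    g_b = gamma.data if param_shape is None else gamma.data.reshape(param_shape)
    b_b = beta.data if param_shape is None else beta.data.reshape(param_shape)
    out = xhat * g_b + b_b

    def backward(g):
        if gamma.requires_grad:
            gg = _unbroadcast(g * xhat, g_b.shape)
            gamma._accumulate(gg.reshape(gamma.shape))
        if beta.requires_grad:
            gb = _unbroadcast(g, b_b.shape)
            beta._accumulate(gb.reshape(beta.shape))
        if x.requires_grad:
            dxhat = g * g_b
            if stats_from_x:
                m1 = dxhat.mean(axis=axes, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
                x._accumulate(inv * (dxhat - m1 - xhat * m2))
            else:
                x._accumulate(inv * dxhat)

    return Tensor._result(out, (x, gamma, beta), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 1-D convolution (cross-correlation).

    x: (B, C_in, L); weight: (C_out, C_in // groups, K); bias: (C_out,).
    Returns (B, C_out, (L + 2*padding - K)//stride + 1).  Dense (groups=1)
    convolutions run as an im2col matmul; depthwise (groups = C_in = C_out)
    as k fused multiply-adds; anything else falls back to einsum.
    """
    batch, c_in, length = x.shape
    c_out, c_in_g, k = weight.shape
    if c_in % groups or c_out % groups or c_in // groups != c_in_g:
        raise ValueError(
            f"channel/group mismatch: x has {c_in} channels, weight expects "
            f"{c_in_g} per group with {groups} groups")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    lp = xp.shape[-1]
    out_len = (lp - k) // stride + 1
    if out_len < 1:
        raise ValueError(f"input length {length} too short for kernel {k}")
    s0, s1, s2 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(batch, c_in, k, out_len), strides=(s0, s1, s2, s2 * stride))
    depthwise = groups == c_in == c_out

    if depthwise:
        w = weight.data[:, 0, :]  # (C, K)
        out = np.zeros((batch, c_out, out_len))
        for kk in range(k):
            out += w[None, :, kk, None] * cols[:, :, kk, :]
    elif groups == 1:
        cols2 = np.ascontiguousarray(cols).reshape(batch, c_in * k, out_len)
        w2 = weight.data.reshape(c_out, c_in * k)
        out = np.matmul(w2[None], cols2)
    else:
        cols_g = cols.reshape(batch, groups, c_in_g, k, out_len)
        w_g = weight.data.reshape(groups, c_out // groups, c_in_g, k)
        out = np.einsum("bgikt,goik->bgot", cols_g, w_g,
                        optimize=True).reshape(batch, c_out, out_len)
    if bias is not None:
        out = out + bias.data[None, :, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def _col2im(gcols):
        """Scatter (B, C, K, T) window gradients back onto the input."""
        gxp = np.zeros((batch, c_in, lp))
        for kk in range(k):
            gxp[:, :, kk:kk + stride * out_len:stride] += gcols[:, :, kk, :]
        if padding:
            gxp = gxp[:, :, padding:lp - padding]
        return gxp

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if depthwise:
            w = weight.data[:, 0, :]
            if weight.requires_grad:
                gw = np.stack([(cols[:, :, kk, :] * g).sum(axis=(0, 2))
                               for kk in range(k)], axis=1)
                weight._accumulate(gw[:, None, :])
            if x.requires_grad:
                gcols = np.stack([w[None, :, kk, None] * g
                                  for kk in range(k)], axis=2)
                x._accumulate(_col2im(gcols))
        elif groups == 1:
            cols2 = np.ascontiguousarray(cols).reshape(batch, c_in * k, out_len)
            w2 = weight.data.reshape(c_out, c_in * k)
            if weight.requires_grad:
                gw = np.matmul(g, cols2.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw.reshape(c_out, c_in_g, k))
            if x.requires_grad:
                gcols = np.matmul(w2.T[None], g)
                x._accumulate(_col2im(gcols.reshape(batch, c_in, k, out_len)))
        else:
            cols_g = cols.reshape(batch, groups, c_in_g, k, out_len)
            w_g = weight.data.reshape(groups, c_out // groups, c_in_g, k)
            gg = g.reshape(batch, groups, c_out // groups, out_len)
            if weight.requires_grad:
                gw = np.einsum("bgikt,bgot->goik", cols_g, gg, optimize=True)
                weight._accumulate(gw.reshape(c_out, c_in_g, k))
            if x.requires_grad:
                gcols = np.einsum("goik,bgot->bgikt", w_g, gg, optimize=True)
                x._accumulate(_col2im(gcols.reshape(batch, c_in, k, out_len)))

    return Tensor._result(out, parents, backward)
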
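"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, sized for the models in
this package: affine and convolutional encoders, linear decoders, and the
pathwise (reparameterized) sampling paths that require gradients to flow
through stochastic nodes. Tensors wrap float64 numpy arrays; calling
:meth:`Tensor.backward` on a scalar accumulates ``.grad`` on every tensor
created with ``requires_grad=True``.

Broadcasting follows numpy semantics; gradients are summed back over
broadcast axes. Only the operations the package needs are implemented.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "sigmoid", "relu", "softmax", "log_softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 array and its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
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

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = lambda: backward(out)
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep (cumsum chains)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._prev:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(out):
            if self.requires_grad:
                self._accumulate(out.grad)
            if other.requires_grad:
                other._accumulate(out.grad)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(out):
            if self.requires_grad:
                self._accumulate(out.grad * other.data)
            if other.requires_grad:
                other._accumulate(out.grad * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        def bwd(out):
            self._accumulate(-out.grad)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(out):
            if self.requires_grad:
                self._accumulate(out.grad / other.data)
            if other.requires_grad:
                other._accumulate(-out.grad * self.data / other.data ** 2)

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")

        def bwd(out):
            self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data ** exponent, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(out):
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        return self._make(self.data @ other.data, (self, other), bwd)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        data = np.exp(self.data)

        def bwd(out):
            self._accumulate(out.grad * data)

        return self._make(data, (self,), bwd)

    def log(self):
        def bwd(out):
            self._accumulate(out.grad / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        def bwd(out):
            self._accumulate(out.grad * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bwd)

    def clip(self, lo: float | None, hi: float | None):
        """Clamp values; gradient is 1 inside the range, 0 outside."""
        data = np.clip(self.data, lo, hi)
        inside = np.ones_like(self.data)
        if lo is not None:
            inside = inside * (self.data >= lo)
        if hi is not None:
            inside = inside * (self.data <= hi)

        def bwd(out):
            self._accumulate(out.grad * inside)

        return self._make(data, (self,), bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(out):
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.data.shape))

        return self._make(data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def cumsum(self, axis: int = 0):
        def bwd(out):
            # reverse cumulative sum along the same axis
            g = np.flip(np.cumsum(np.flip(out.grad, axis=axis), axis=axis), axis=axis)
            self._accumulate(g)

        return self._make(np.cumsum(self.data, axis=axis), (self,), bwd)

    # ----------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(out):
            self._accumulate(out.grad.reshape(self.data.shape))

        return self._make(self.data.reshape(shape), (self,), bwd)

    @property
    def T(self):
        def bwd(out):
            self._accumulate(out.grad.T)

        return self._make(self.data.T, (self,), bwd)

    def __getitem__(self, idx):
        def bwd(out):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, out.grad)
            self._accumulate(grad)

        return self._make(self.data[idx], (self,), bwd)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True`` by construction)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ------------------------------------------------------------------ functions
def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -700.0, 700.0)))

    def bwd(out):
        x._accumulate(out.grad * data * (1.0 - data))

    return x._make(data, (x,), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(out):
        x._accumulate(out.grad * mask)

    return x._make(x.data * mask, (x,), bwd)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = np.max(x.data, axis=axis, keepdims=True)
    lse = m + np.log(np.sum(np.exp(x.data - m), axis=axis, keepdims=True))
    data = x.data - lse
    p = np.exp(data)

    def bwd(out):
        x._accumulate(out.grad - p * out.grad.sum(axis=axis, keepdims=True))

    return x._make(data, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel/stride/padding.

    Implemented with im2col + matmul; the backward pass scatters gradients
    back with an explicit col2im loop over the (small) kernel footprint.
    """
    B, C, H, W = x.shape
    F, Cw, k, _ = weight.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1

    sB, sC, sH, sW = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C, k, k, Ho, Wo),
        strides=(sB, sC, sH, sW, sH * stride, sW * stride),
    ).reshape(B, C * k * k, Ho * Wo)  # copy happens here

    Wm = weight.data.reshape(F, C * k * k)
    out_data = np.einsum("fc,bcl->bfl", Wm, cols).reshape(B, F, Ho, Wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, F, 1, 1)

    parents = [x, weight] + ([bias] if bias is not None else [])

    def bwd(out):
        g = out.grad.reshape(B, F, Ho * Wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            gW = np.einsum("bfl,bcl->fc", g, cols)
            weight._accumulate(gW.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("fc,bfl->bcl", Wm, g).reshape(B, C, k, k, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return x._make(out_data, parents, bwd)


class Adam:
    """Adam optimizer over a list of :class:`Parameter` objects."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
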
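"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based scalar-output autodiff core: each ``Tensor`` wraps an ndarray and
remembers how it was produced; calling :meth:`Tensor.backward` on a scalar
loss propagates gradients to every parameter that participated.  Only the
operations the quality-assessment network needs are implemented -- dense
linear algebra, pointwise nonlinearities, reductions, indexing/gather,
concatenation and dilated 2-D convolution -- all in float64.

The engine is deliberately small and sequential: determinism on a single
CPU thread is part of its contract, and the finite-difference gradient
checks in the test-suite pin down its correctness.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

from .errors import ContractError


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = None

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ContractError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                cur, done = stack.pop()
                if done:
                    topo.append(cur)
                    continue
                if id(cur) in seen or not cur.requires_grad:
                    continue
                seen.add(id(cur))
                stack.append((cur, True))
                for p in cur._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic --------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(np.asarray(ga), self.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g) if g.ndim else a * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(np.asarray(gb), other.shape))

        out._backward = bw
        return out

    # -- pointwise functions -----------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        s = _sp.expit(self.data)
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def gelu(self):
        """Gaussian-error linear unit (tanh approximation)."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), _parents=(self,))

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            self._accumulate(
                g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner)
            )

        out._backward = bw
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * _sp.expit(self.data))
        return out

    def sin(self):
        out = Tensor(np.sin(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.cos(self.data))
        return out

    def cos(self):
        out = Tensor(np.cos(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(-g * np.sin(self.data))
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * sign)
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(tuple(inverse)))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))

    def bw(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, k, axis=axis))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, axis: int = -1,
               eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=axis, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=axis, keepdims=True)
    return gamma * (centered / (var + eps).sqrt()) + beta


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, dilation: int = 1) -> Tensor:
    """Same-padding 2-D convolution: ``(Ci,H,W) x (Co,Ci,k,k) -> (Co,H,W)``.

    Implemented as an im2col matmul; the column matrix is assembled from the
    ``k*k`` shifted views of the padded input (and scattered back the same
    way in the backward pass), which keeps both directions BLAS-bound.
    """
    ci, h, w = x.shape
    co, ci_w, kh, kw = weight.shape
    if ci != ci_w or kh != kw:
        raise ContractError("conv2d weight shape mismatch")
    k = kh
    pad = dilation * (k - 1) // 2
    if k == 1:
        patches = x.data.reshape(ci, h * w)
    else:
        xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
        patches = np.empty((ci, k * k, h * w))
        t = 0
        for kr in range(k):
            for kc in range(k):
                r0, c0 = kr * dilation, kc * dilation
                patches[:, t, :] = xp[:, r0 : r0 + h, c0 : c0 + w].reshape(ci, h * w)
                t += 1
        patches = patches.reshape(ci * k * k, h * w)
    wmat = weight.data.reshape(co, ci * k * k)
    out_data = (wmat @ patches).reshape(co, h, w) + bias.data[:, None, None]
    out = Tensor(out_data, _parents=(x, weight, bias))

    def bw(g):
        gmat = g.reshape(co, h * w)
        if weight.requires_grad:
            weight._accumulate((gmat @ patches.T).reshape(weight.shape))
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2)))
        if x.requires_grad:
            gp = (wmat.T @ gmat).reshape(ci, k * k, h * w)
            if k == 1:
                x._accumulate(gp.reshape(ci, h, w))
                return
            gx = np.zeros((ci, h + 2 * pad, w + 2 * pad))
            t = 0
            for kr in range(k):
                for kc in range(k):
                    r0, c0 = kr * dilation, kc * dilation
                    gx[:, r0 : r0 + h, c0 : c0 + w] += gp[:, t, :].reshape(ci, h, w)
                    t += 1
            x._accumulate(gx[:, pad : pad + h, pad : pad + w])

    out._backward = bw
    return out


def parameter(data, rng: np.random.Generator | None = None,
              fan_in: int | None = None) -> Tensor:
    """Create a trainable tensor; with ``rng`` given, Glorot-style init."""
    if rng is not None:
        shape = data if isinstance(data, tuple) else tuple(data)
        fi = fan_in if fan_in is not None else (shape[-2] if len(shape) > 1 else shape[0])
        scale = 1.0 / np.sqrt(max(1, fi))
        data = rng.uniform(-scale, scale, size=shape)
    return Tensor(data, requires_grad=True)
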
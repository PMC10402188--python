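"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each operation builds a :class:`Tensor` holding a
``float64`` ndarray plus a closure that propagates the upstream gradient to its
parents.  It powers two things in this package:

* exact gradients of the pose score with respect to translation / rotation /
  torsion parameters (consumed by the L-BFGS pose minimizer), and
* the Twister encoder together with its Adam training loop.

Only the operations those two consumers need are implemented.  Everything is
double precision and single-threaded NumPy, so results are deterministic.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "backward",
    "concat",
    "cross",
    "layer_norm",
    "leaky_relu",
    "matmul",
    "softmax",
    "where",
    "Adam",
]


class Tensor:
    """Node in the autodiff graph.

    ``value`` is always a float64 ndarray.  ``grad`` is filled in (with the
    same shape) by :func:`backward` for every node with ``requires_grad``.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_bw")

    # make ndarray <op> Tensor defer to the Tensor's reflected operator
    __array_priority__ = 1000
    __array_ufunc__ = None

    def __init__(
        self,
        value,
        requires_grad: bool = False,
        parents: tuple = (),
        bw: Callable[[np.ndarray], None] | None = None,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._bw = bw

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


class Parameter(Tensor):
    """A leaf tensor that Adam updates in place."""

    def __init__(self, value):
        super().__init__(value, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64, copy=True)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value + b.value

    def bw(g):
        _accum(a, _unbroadcast(g, a.value.shape))
        _accum(b, _unbroadcast(g, b.value.shape))

    return Tensor(out_val, parents=(a, b), bw=bw)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, -g)

    return Tensor(-a.value, parents=(a,), bw=bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value * b.value

    def bw(g):
        _accum(a, _unbroadcast(g * b.value, a.value.shape))
        _accum(b, _unbroadcast(g * a.value, b.value.shape))

    return Tensor(out_val, parents=(a, b), bw=bw)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value / b.value

    def bw(g):
        _accum(a, _unbroadcast(g / b.value, a.value.shape))
        _accum(b, _unbroadcast(-g * a.value / (b.value**2), b.value.shape))

    return Tensor(out_val, parents=(a, b), bw=bw)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_val = a.value**exponent

    def bw(g):
        _accum(a, g * exponent * a.value ** (exponent - 1))

    return Tensor(out_val, parents=(a,), bw=bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_val = np.exp(a.value)

    def bw(g):
        _accum(a, g * out_val)

    return Tensor(out_val, parents=(a,), bw=bw)


def log(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, g / a.value)

    return Tensor(np.log(a.value), parents=(a,), bw=bw)


def sqrt(a) -> Tensor:
    a = as_tensor(a)
    out_val = np.sqrt(a.value)

    def bw(g):
        _accum(a, g * 0.5 / out_val)

    return Tensor(out_val, parents=(a,), bw=bw)


def sin(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, g * np.cos(a.value))

    return Tensor(np.sin(a.value), parents=(a,), bw=bw)


def cos(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, -g * np.sin(a.value))

    return Tensor(np.cos(a.value), parents=(a,), bw=bw)


def leaky_relu(a, slope: float = 0.1) -> Tensor:
    a = as_tensor(a)
    mask = a.value >= 0
    out_val = np.where(mask, a.value, slope * a.value)

    def bw(g):
        _accum(a, np.where(mask, g, slope * g))

    return Tensor(out_val, parents=(a,), bw=bw)


def where(mask: np.ndarray, a, b) -> Tensor:
    """Select elementwise by a constant boolean mask (broadcastable)."""
    a, b = as_tensor(a), as_tensor(b)
    out_val = np.where(mask, a.value, b.value)

    def bw(g):
        _accum(a, _unbroadcast(np.where(mask, g, 0.0), a.value.shape))
        _accum(b, _unbroadcast(np.where(mask, 0.0, g), b.value.shape))

    return Tensor(out_val, parents=(a, b), bw=bw)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.value.shape

    def bw(g):
        _accum(a, g.reshape(old))

    return Tensor(a.value.reshape(shape), parents=(a,), bw=bw)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def bw(g):
        _accum(a, g.transpose(inv))

    return Tensor(a.value.transpose(axes), parents=(a,), bw=bw)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accum(a, _unbroadcast(g, a.value.shape))

    return Tensor(np.broadcast_to(a.value, shape), parents=(a,), bw=bw)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        gg = np.zeros_like(a.value)
        np.add.at(gg, idx, g)
        _accum(a, gg)

    return Tensor(a.value[idx], parents=(a,), bw=bw)


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(
        np.concatenate([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        bw=bw,
    )


def stack(tensors: Sequence, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g):
        for i, t in enumerate(tensors):
            _accum(t, np.take(g, i, axis=axis))

    return Tensor(
        np.stack([t.value for t in tensors], axis=axis),
        parents=tuple(tensors),
        bw=bw,
    )


# ---------------------------------------------------------------------------
# reductions & linear algebra
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_val = a.value.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.value.shape).copy())

    return Tensor(out_val, parents=(a,), bw=bw)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.value.size if axis is None else np.prod(
        [a.value.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def matmul(a, b) -> Tensor:
    """Batched matrix product (both operands at least 2-D)."""
    a, b = as_tensor(a), as_tensor(b)
    out_val = a.value @ b.value

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g @ np.swapaxes(b.value, -1, -2), a.value.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(np.swapaxes(a.value, -1, -2) @ g, b.value.shape))

    return Tensor(out_val, parents=(a, b), bw=bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.value - a.value.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _accum(a, s * (g - dot))

    return Tensor(s, parents=(a,), bw=bw)


def layer_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    x = as_tensor(x)
    mu = tmean(x, axis=-1, keepdims=True)
    centered = x - mu
    var = tmean(mul(centered, centered), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(centered, inv), gain), bias)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def cross(a, b) -> Tensor:
    """Cross product along the last axis (broadcasting allowed)."""
    a, b = as_tensor(a), as_tensor(b)
    out_val = np.cross(a.value, b.value)

    def bw(g):
        _accum(a, _unbroadcast(np.cross(b.value, g), a.value.shape))
        _accum(b, _unbroadcast(np.cross(g, a.value), b.value.shape))

    return Tensor(out_val, parents=(a, b), bw=bw)


_ROT_EPS = 1e-6  # switch to series below this squared angle


def rot_coeff_a(s) -> Tensor:
    """sin(theta)/theta as a smooth function of s = theta^2.

    The series branch keeps the value and derivative finite at s = 0, which
    matters because pose optimization starts from a zero rotation vector.
    """
    s = as_tensor(s)
    sv = s.value
    small = sv < _ROT_EPS
    t = np.sqrt(np.where(small, 1.0, sv))
    val = np.where(small, 1.0 - sv / 6.0 + sv**2 / 120.0, np.sin(t) / t)
    deriv = np.where(
        small,
        -1.0 / 6.0 + sv / 60.0,
        (t * np.cos(t) - np.sin(t)) / (2.0 * t**3),
    )

    def bw(g):
        _accum(s, g * deriv)

    return Tensor(val, parents=(s,), bw=bw)


def rot_coeff_b(s) -> Tensor:
    """(1 - cos(theta))/theta^2 as a smooth function of s = theta^2."""
    s = as_tensor(s)
    sv = s.value
    small = sv < _ROT_EPS
    t = np.sqrt(np.where(small, 1.0, sv))
    safe_s = np.where(small, 1.0, sv)
    val = np.where(small, 0.5 - sv / 24.0 + sv**2 / 720.0, (1.0 - np.cos(t)) / safe_s)
    deriv = np.where(
        small,
        -1.0 / 24.0 + sv / 360.0,
        (t * np.sin(t) / 2.0 - (1.0 - np.cos(t))) / safe_s**2,
    )

    def bw(g):
        _accum(s, g * deriv)

    return Tensor(val, parents=(s,), bw=bw)


def rotate_rotvec(vecs, rotvec) -> Tensor:
    """Rotate row vectors ``vecs`` (..., 3) by an axis-angle vector (3,).

    Rodrigues in the form R v = v + a (r x v) + b (r x (r x v)) with
    a = sin(t)/t and b = (1-cos(t))/t^2, smooth through t = 0.
    """
    vecs, rotvec = as_tensor(vecs), as_tensor(rotvec)
    s = tsum(mul(rotvec, rotvec))
    a = rot_coeff_a(s)
    b = rot_coeff_b(s)
    rx = cross(rotvec, vecs)
    rrx = cross(rotvec, rx)
    return add(vecs, add(mul(a, rx), mul(b, rrx)))


# ---------------------------------------------------------------------------
# backward pass & optimizer
# ---------------------------------------------------------------------------

def backward(out: Tensor) -> None:
    """Backpropagate d(out)/d(leaf) into every ``requires_grad`` leaf.

    ``out`` may have any shape; the seed gradient is all ones (callers
    normally reduce to a scalar loss first).
    """
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack_ = [out]
    # iterative DFS post-order (graphs can be deep for many torsions/blocks)
    visit_stack: list[tuple[Tensor, bool]] = [(out, False)]
    while visit_stack:
        node, processed = visit_stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        visit_stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen and p.requires_grad:
                visit_stack.append((p, False))
    del stack_
    out.grad = np.ones_like(out.value)
    for node in reversed(topo):
        if node._bw is not None and node.grad is not None:
            node._bw(node.grad)


class Adam:
    """Standard Adam on a list of :class:`Parameter` objects."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
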
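"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports higher-order differentiation: every vector-Jacobian product is
itself expressed with :class:`Tensor` operations, so calling :func:`grad`
with ``create_graph=True`` yields gradients that can be differentiated
again.  This is required to train with a penalty on the input-output
Jacobian, whose parameter gradient is a second derivative of the forward
pass.

Only the small set of operations needed by the decoding network is
implemented (affine maps, leaky rectifier, normalization arithmetic,
reductions, absolute value).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "matmul",
    "leaky_relu",
    "absolute",
    "mean",
    "tsum",
    "power",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        # sequence of (parent Tensor, vjp callable) pairs
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __truediv__(self, other):
        return mul(self, power(as_tensor(other), -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    """Create a result tensor, recording only parents that need grad."""
    tracked = tuple((p, fn) for p, fn in parents if p.requires_grad)
    out = Tensor(data, requires_grad=bool(tracked))
    out._parents = tracked
    return out


# -- shape plumbing -----------------------------------------------------

def sum_to_shape(t: Tensor, shape) -> Tensor:
    """Inverse of numpy broadcasting: reduce ``t`` down to ``shape``."""
    t = as_tensor(t)
    if t.data.shape == tuple(shape):
        return t
    data = t.data
    # collapse leading broadcast axes
    extra = data.ndim - len(shape)
    if extra > 0:
        data = data.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and data.shape[i] != 1)
    if axes:
        data = data.sum(axis=axes, keepdims=True)
    src = t
    return _make(data, [(src, lambda g, shp=src.data.shape: broadcast_to(g, shp))])


def broadcast_to(t: Tensor, shape) -> Tensor:
    t = as_tensor(t)
    if t.data.shape == tuple(shape):
        return t
    data = np.broadcast_to(t.data, shape)
    src = t
    return _make(data, [(src, lambda g, shp=src.data.shape: sum_to_shape(g, shp))])


def reshape(t: Tensor, shape) -> Tensor:
    t = as_tensor(t)
    src = t
    return _make(
        t.data.reshape(shape),
        [(src, lambda g, shp=src.data.shape: reshape(g, shp))],
    )


# -- arithmetic ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data + b.data,
        [
            (a, lambda g, shp=a.data.shape: sum_to_shape(g, shp)),
            (b, lambda g, shp=b.data.shape: sum_to_shape(g, shp)),
        ],
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data * b.data,
        [
            (a, lambda g, o=b, shp=a.data.shape: sum_to_shape(mul(g, o), shp)),
            (b, lambda g, o=a, shp=b.data.shape: sum_to_shape(mul(g, o), shp)),
        ],
    )


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return _make(
        a.data @ b.data,
        [
            (a, lambda g, o=b: matmul(g, transpose(o))),
            (b, lambda g, o=a: matmul(transpose(o), g)),
        ],
    )


def transpose(t: Tensor) -> Tensor:
    t = as_tensor(t)
    return _make(t.data.T, [(t, lambda g: transpose(g))])


def power(t: Tensor, p: float) -> Tensor:
    t = as_tensor(t)
    return _make(
        t.data ** p,
        [(t, lambda g, src=t, q=p: mul(g, mul(q, power(src, q - 1.0))))],
    )


def absolute(t: Tensor) -> Tensor:
    t = as_tensor(t)
    sign = np.sign(t.data)  # constant w.r.t. differentiation (a.e.)
    return _make(np.abs(t.data), [(t, lambda g, s=sign: mul(g, s))])


def leaky_relu(t: Tensor, negative_slope: float = 0.01) -> Tensor:
    t = as_tensor(t)
    slope = np.where(t.data > 0, 1.0, negative_slope)
    return _make(
        np.where(t.data > 0, t.data, negative_slope * t.data),
        [(t, lambda g, s=slope: mul(g, s))],
    )


def tsum(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = as_tensor(t)
    data = t.data.sum(axis=axis, keepdims=keepdims)
    src = t

    def vjp(g, axis=axis, keepdims=keepdims, shp=src.data.shape):
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            kd_shape = list(g.data.shape)
            for ax in sorted(ax % len(shp) for ax in axes):
                kd_shape.insert(ax, 1)
            g = reshape(g, tuple(kd_shape))
        return broadcast_to(g, shp)

    return _make(data, [(src, vjp)])


def mean(t: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    t = as_tensor(t)
    n = t.data.size if axis is None else np.prod(
        [t.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(t, axis=axis, keepdims=keepdims), 1.0 / float(n))


# -- backward traversal -------------------------------------------------

def _topo_order(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            stack.append((parent, False))
    return order


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of a scalar-or-seeded ``output`` w.r.t. each of ``inputs``.

    When ``create_graph`` is false, the returned tensors are detached
    constants; when true they carry the graph needed for differentiating
    through them again.
    """
    inputs = list(inputs)
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("grad of a non-scalar output requires grad_output")
        seed = Tensor(np.ones_like(output.data))
    else:
        seed = as_tensor(grad_output)

    grads = {id(output): seed}
    for node in reversed(_topo_order(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node in inputs or any(node is x for x in inputs):
            grads[id(node)] = g  # keep grads of requested leaves
        for parent, vjp in node._parents:
            contrib = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else add(prev, contrib)
        if node._parents:
            # retain for requested non-leaf inputs
            if any(node is x for x in inputs):
                grads[id(node)] = g

    out = []
    for x in inputs:
        g = grads.get(id(x))
        if g is None:
            g = Tensor(np.zeros_like(x.data))
        if not create_graph:
            g = Tensor(g.data)
        out.append(g)
    return out
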
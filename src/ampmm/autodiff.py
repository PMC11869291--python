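"""Minimal reverse-mode automatic differentiation on numpy arrays.

The backward pass is itself built from the same differentiable primitives,
so gradients are ``Var`` graphs and can be differentiated again.  This is
what allows a loss containing forces (forces being -dV/dR) to be
differentiated with respect to network parameters.

Only the primitives the potential and its training actually use are
implemented: elementwise arithmetic, trig/exp, reductions, dense layers
(``dot``), two-operand contractions (``contract``), gather/scatter
(``take``/``untake``), concatenation and masking.  Graphs run in float64
or float32; python-scalar constants never promote a float32 graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var", "var", "grad", "add", "mul", "sub", "div", "neg", "power",
    "exp", "log", "sqrt", "sin", "cos", "arccos", "atan2", "vsum", "vmean",
    "dot", "take", "untake", "concat", "contract", "where", "broadcast_to", "reshape",
    "transpose2", "slice_last",
]


class Var:
    """Node in the computation graph: an ndarray plus parent edges."""

    __slots__ = ("data", "parents")

    def __init__(self, data, parents=()):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
        if data.dtype not in (np.float64, np.float32):
            data = data.astype(np.float64)
        self.data = data
        self.parents = parents

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(_lift(other), self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_lift(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return vsum(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.data.shape})"


def var(x):
    """Lift an array-like into a leaf Var."""
    return x if isinstance(x, Var) else Var(x)


_lift = var


def _unbroadcast(g: Var, shape) -> Var:
    """Reduce gradient ``g`` to ``shape`` by summing broadcast axes."""
    if g.data.shape == tuple(shape):
        return g
    nd = len(shape)
    while g.data.ndim > nd:
        g = vsum(g, axis=0)
    axes = tuple(i for i in range(nd) if shape[i] == 1 and g.data.shape[i] != 1)
    if axes:
        g = vsum(g, axis=axes, keepdims=True)
    return g


# -- elementwise -------------------------------------------------------
#
# Binary ops accept raw scalars/ndarrays for the non-differentiated side;
# python scalars stay "weak" so float32 graphs are not promoted.

def add(a, b):
    if not isinstance(b, Var):
        a = _lift(a)
        return Var(a.data + b, ((a, lambda g: _unbroadcast(g, a.data.shape)),))
    if not isinstance(a, Var):
        return add(b, a)
    return Var(a.data + b.data, (
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(g, b.data.shape)),
    ))


def sub(a, b):
    if not isinstance(b, Var):
        a = _lift(a)
        return Var(a.data - b, ((a, lambda g: _unbroadcast(g, a.data.shape)),))
    if not isinstance(a, Var):
        return Var(a - b.data, (
            (b, lambda g: _unbroadcast(neg(g), b.data.shape)),))
    return Var(a.data - b.data, (
        (a, lambda g: _unbroadcast(g, a.data.shape)),
        (b, lambda g: _unbroadcast(neg(g), b.data.shape)),
    ))


def neg(a):
    a = _lift(a)
    return Var(-a.data, ((a, lambda g: neg(g)),))


def mul(a, b):
    if not isinstance(b, Var):
        a = _lift(a)
        return Var(a.data * b, (
            (a, lambda g: _unbroadcast(mul(g, b), a.data.shape)),))
    if not isinstance(a, Var):
        return mul(b, a)
    return Var(a.data * b.data, (
        (a, lambda g: _unbroadcast(mul(g, b), a.data.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.data.shape)),
    ))


def div(a, b):
    if not isinstance(b, Var):
        a = _lift(a)
        return Var(a.data / b, (
            (a, lambda g: _unbroadcast(div(g, b), a.data.shape)),))
    if not isinstance(a, Var):
        return Var(a / b.data, (
            (b, lambda g: _unbroadcast(
                neg(div(mul(g, a), mul(b, b))), b.data.shape)),))
    return Var(a.data / b.data, (
        (a, lambda g: _unbroadcast(div(g, b), a.data.shape)),
        (b, lambda g: _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape)),
    ))


def power(a, p):
    a = _lift(a)
    p = float(p)
    return Var(a.data ** p, (
        (a, lambda g: mul(g, mul(p, power(a, p - 1.0)))),
    ))


def exp(a):
    a = _lift(a)
    out = Var(np.exp(a.data))
    out.parents = ((a, lambda g: mul(g, out)),)
    return out


def log(a):
    a = _lift(a)
    return Var(np.log(a.data), ((a, lambda g: div(g, a)),))


def sqrt(a):
    a = _lift(a)
    out = Var(np.sqrt(a.data))
    out.parents = ((a, lambda g: div(g, mul(2.0, out))),)
    return out


def sin(a):
    a = _lift(a)
    return Var(np.sin(a.data), ((a, lambda g: mul(g, cos(a))),))


def cos(a):
    a = _lift(a)
    return Var(np.cos(a.data), ((a, lambda g: neg(mul(g, sin(a)))),))


def arccos(a):
    a = _lift(a)
    return Var(np.arccos(a.data), (
        (a, lambda g: neg(div(g, sqrt(sub(1.0, mul(a, a)))))),
    ))


def atan2(y, x):
    y, x = _lift(y), _lift(x)
    return Var(np.arctan2(y.data, x.data), (
        (y, lambda g: _unbroadcast(
            div(mul(g, x), add(mul(x, x), mul(y, y))), y.data.shape)),
        (x, lambda g: _unbroadcast(
            neg(div(mul(g, y), add(mul(x, x), mul(y, y)))), x.data.shape)),
    ))


# -- reductions / shape ------------------------------------------------

def vsum(a, axis=None, keepdims=False):
    a = _lift(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return broadcast_to(g, a.data.shape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            kshape = list(a.data.shape)
            for ax in axes:
                kshape[ax] = 1
            g = reshape(g, tuple(kshape))
        return broadcast_to(g, a.data.shape)

    return Var(data, ((a, vjp),))


def vmean(a, axis=None, keepdims=False):
    a = _lift(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(vsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def broadcast_to(a, shape):
    a = _lift(a)
    shape = tuple(shape)
    if a.data.shape == shape:
        return a
    # read-only view; every op treats inputs as immutable
    return Var(np.broadcast_to(a.data, shape), (
        (a, lambda g: _unbroadcast(g, a.data.shape)),
    ))


def reshape(a, shape):
    a = _lift(a)
    shape = tuple(shape)
    return Var(a.data.reshape(shape), (
        (a, lambda g: reshape(g, a.data.shape)),
    ))


def transpose2(a):
    """Transpose of a 2-D array."""
    a = _lift(a)
    return Var(a.data.T, ((a, lambda g: transpose2(g)),))


# -- linear algebra ----------------------------------------------------

def dot(x, w):
    """``x @ w`` for x of shape (..., n_in) and 2-D w of shape (n_in, n_out)."""
    x, w = _lift(x), _lift(w)
    return Var(np.matmul(x.data, w.data), (
        (x, lambda g: dot(g, transpose2(w))),
        (w, lambda g: _tdot(x, g)),
    ))


def _tdot(x, g):
    """sum over leading axes of x[..., i] * g[..., o] -> (i, o)."""
    xi = x.data.reshape(-1, x.data.shape[-1])
    gi = g.data.reshape(-1, g.data.shape[-1])
    return Var(xi.T @ gi, (
        (x, lambda c: dot(g, transpose2(c))),
        (g, lambda c: dot(x, c)),
    ))


def contract(spec: str, a, b):
    """Two-operand einsum with automatically derived vjps.

    Every index of each operand must appear in the output or the other
    operand (no internal traces), which makes the adjoint another
    ``contract`` call — so contractions stay differentiable to any order
    without materializing broadcast intermediates.
    """
    a, b = _lift(a), _lift(b)
    in_spec, out_spec = spec.split("->")
    sa, sb = in_spec.split(",")
    return Var(np.einsum(spec, a.data, b.data), (
        (a, lambda g: contract(f"{out_spec},{sb}->{sa}", g, b)),
        (b, lambda g: contract(f"{out_spec},{sa}->{sb}", g, a)),
    ))


# -- gather / scatter --------------------------------------------------

def take(a, idx, axis):
    """Gather slices ``a[..., idx, ...]`` along ``axis`` (idx: int ndarray)."""
    a = _lift(a)
    idx = np.asarray(idx)
    size = a.data.shape[axis]
    return Var(np.take(a.data, idx, axis=axis), (
        (a, lambda g: untake(g, idx, axis, size)),
    ))


def untake(v, idx, axis, size):
    """Scatter-add inverse of :func:`take`: result[..., k, ...] = sum over
    positions where idx == k of v.

    Implemented by sorting the (small) index list and segment-summing the
    payload, which is much faster than ``np.add.at`` on large arrays.
    """
    v = _lift(v)
    idx = np.asarray(idx)
    shape = list(v.data.shape)
    shape[axis] = size
    out = np.zeros(shape, dtype=v.data.dtype)
    if idx.size:
        vs, si = v.data, idx
        if np.any(np.diff(idx) < 0):
            order = np.argsort(idx, kind="stable")
            vs = np.take(v.data, order, axis=axis)
            si = idx[order]
        uniq, starts, counts = np.unique(si, return_index=True,
                                         return_counts=True)
        if np.all(counts == counts[0]):
            k = int(counts[0])
            shaped = vs.reshape(vs.shape[:axis] + (len(uniq), k)
                                + vs.shape[axis + 1:])
            sums = shaped.sum(axis=axis + 1)
        else:
            sums = np.add.reduceat(vs, starts, axis=axis)
        out[(slice(None),) * axis + (uniq,)] = sums
    return Var(out, ((v, lambda g: take(g, idx, axis)),))


# -- assorted ----------------------------------------------------------

def concat(vs, axis):
    vs = [_lift(v) for v in vs]
    data = np.concatenate([v.data for v in vs], axis=axis)
    offsets = np.cumsum([0] + [v.data.shape[axis] for v in vs])

    parents = []
    for k, v in enumerate(vs):
        lo, hi = offsets[k], offsets[k + 1]

        def vjp(g, lo=lo, hi=hi):
            key = (slice(None),) * (axis % g.data.ndim) + (slice(lo, hi),)
            return _slice(g, key)

        parents.append((v, vjp))
    return Var(data, tuple(parents))


def _slice(a, key):
    a = _lift(a)
    shape = a.data.shape
    return Var(a.data[key].copy(), ((a, lambda g: _unslice(g, key, shape)),))


def _unslice(v, key, shape):
    """Scatter ``v`` into zeros of ``shape`` at ``key`` (inverse of _slice)."""
    v = _lift(v)
    out = np.zeros(shape, dtype=v.data.dtype)
    out[key] = v.data
    return Var(out, ((v, lambda g: _slice(g, key)),))


def slice_last(a, lo, hi):
    """View a[..., lo:hi] (differentiable)."""
    return _slice(a, (Ellipsis, slice(lo, hi)))


def where(cond, a, b):
    """Elementwise select with a *constant* boolean condition; either
    branch may be a raw scalar/ndarray constant."""
    cond = np.asarray(cond)
    parents = []
    da = a.data if isinstance(a, Var) else a
    db = b.data if isinstance(b, Var) else b
    if isinstance(a, Var):
        parents.append((a, lambda g: _unbroadcast(where(cond, g, 0.0),
                                                  a.data.shape)))
    if isinstance(b, Var):
        parents.append((b, lambda g: _unbroadcast(where(cond, 0.0, g),
                                                  b.data.shape)))
    return Var(np.where(cond, da, db), tuple(parents))


# -- reverse pass ------------------------------------------------------

def grad(output: Var, inputs, cotangent=None):
    """Gradients of scalar-or-seeded ``output`` w.r.t. each Var in ``inputs``.

    Returns a list of Vars (differentiable again).  Inputs that the output
    does not depend on get a zero gradient of matching shape.
    """
    seed = (cotangent if cotangent is not None
            else Var(np.ones(output.data.shape, dtype=output.data.dtype)))

    # iterative topological order
    topo, visited, stack = [], set(), [(output, False)]
    while stack:
        node, done = stack.pop()
        if done:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if id(p) not in visited:
                stack.append((p, False))

    grads = {id(output): seed}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for p, vjp in node.parents:
            contrib = vjp(g)
            prev = grads.get(id(p))
            grads[id(p)] = contrib if prev is None else add(prev, contrib)

    out = []
    for v in inputs:
        g = grads.get(id(v))
        out.append(g if g is not None
                   else Var(np.zeros(v.data.shape, dtype=v.data.dtype)))
    return out
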
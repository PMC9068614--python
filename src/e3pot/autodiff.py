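"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists to make the potential energy differentiable twice: forces
are ``-dE/dr`` and the training loss contains those forces, so optimizing the
loss requires gradients *of* gradients.  Every vector-Jacobian product below
is therefore written in terms of engine operations (not raw numpy), which
makes the backward pass itself differentiable when ``create_graph=True``.

Only the operations the network needs are implemented; this is not a general
array library.  All data is kept in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "no_grad",
    "concatenate",
    "einsum",
    "segment_sum",
    "where",
    "sin",
    "cos",
    "exp",
    "tanh",
    "sqrt",
    "sigmoid",
    "silu",
]

_GRAD_ENABLED = True
_DTYPE = np.float64


class precision:
    """Context manager setting the working dtype of newly created tensors.

    Double precision is the default (needed by the symmetry and
    finite-difference audits); training switches to single precision, which
    is ample for stochastic optimization and roughly halves the cost of the
    dominant GEMMs."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype)

    def __enter__(self):
        global _DTYPE
        self._prev = _DTYPE
        _DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global _DTYPE
        _DTYPE = self._prev
        return False


class no_grad:
    """Context manager disabling graph recording (used inside plain backward)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.parents = parents
        self.vjp = vjp
        self.requires_grad = requires_grad

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ---- operators ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return take(self, key)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, vjp):
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjp=vjp)
    return Tensor(data)


# ---- broadcasting helper ------------------------------------------------

def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---- arithmetic ----------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(a.data + b.data, (a, b), vjp)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        ga = _unbroadcast(mul(g, b), a.shape) if a.requires_grad else None
        gb = _unbroadcast(mul(g, a), b.shape) if b.requires_grad else None
        return ga, gb

    return _make(a.data * b.data, (a, b), vjp)


def power(a, exponent):
    a = _as_tensor(a)
    exponent = float(exponent)

    def vjp(g):
        return (mul(g, mul(power(a, exponent - 1.0), exponent)),)

    return _make(a.data**exponent, (a,), vjp)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def vjp(g):
        ga = matmul(g, transpose(b)) if a.requires_grad else None
        gb = matmul(transpose(a), g) if b.requires_grad else None
        return ga, gb

    return _make(a.data @ b.data, (a, b), vjp)


def transpose(a):
    a = _as_tensor(a)

    def vjp(g):
        return (transpose(g),)

    return _make(a.data.T, (a,), vjp)


def swapaxes(a):
    """Swap the last two axes (matrix transpose of a batch of matrices)."""
    a = _as_tensor(a)

    def vjp(g):
        return (swapaxes(g),)

    return _make(np.swapaxes(a.data, -1, -2), (a,), vjp)


def _unbroadcast_bmm(g, shape):
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, s in enumerate(shape[:-2]) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


def bmm(a, b):
    """Batched matrix multiply with numpy broadcasting on leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        ga = _unbroadcast_bmm(bmm(g, swapaxes(b)), a.shape) if a.requires_grad else None
        gb = _unbroadcast_bmm(bmm(swapaxes(a), g), b.shape) if b.requires_grad else None
        return ga, gb

    return _make(np.matmul(a.data, b.data), (a, b), vjp)


def channel_mix(x, W):
    """``out[a,o,m] = sum_c x[a,c,m] W[c,o]`` — atom-wise linear channel
    mixing with weights shared over the representation index m."""
    x, W = _as_tensor(x), _as_tensor(W)

    def vjp(g):
        gx = channel_mix(g, transpose(W)) if x.requires_grad else None
        gW = channel_outer(x, g) if W.requires_grad else None
        return gx, gW

    out = np.tensordot(x.data, W.data, axes=([1], [0])).transpose(0, 2, 1)
    return _make(out, (x, W), vjp)


def channel_outer(x, g):
    """Adjoint of channel_mix w.r.t. the weight: ``sum_{a,m} x[a,c,m] g[a,o,m]``."""
    x, g = _as_tensor(x), _as_tensor(g)

    def vjp(h):
        gx = channel_mix(g, transpose(h)) if x.requires_grad else None
        gg = channel_mix(x, h) if g.requires_grad else None
        return gx, gg

    out = np.tensordot(x.data, g.data, axes=([0, 2], [0, 2]))
    return _make(out, (x, g), vjp)


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None or keepdims:
            return (mul(g, np.ones(a.shape)),)
        ax = tuple(np.atleast_1d(axis))
        gshape = list(out.shape)
        for i in sorted(i % a.ndim for i in ax):
            gshape.insert(i, 1)
        return (mul(reshape(g, tuple(gshape)), np.ones(a.shape)),)

    return _make(out, (a,), vjp)


def reshape(a, shape):
    a = _as_tensor(a)

    def vjp(g):
        return (reshape(g, a.shape),)

    return _make(a.data.reshape(shape), (a,), vjp)


# ---- indexing ------------------------------------------------------------

def take(a, key):
    """``a[key]`` for basic slices or an integer index array on axis 0."""
    a = _as_tensor(a)
    if isinstance(key, Tensor):
        raise TypeError("index must not be a Tensor")
    if isinstance(key, np.ndarray):
        key = key.astype(np.intp)

    def vjp(g):
        return (scatter(g, key, a.shape),)

    return _make(a.data[key], (a,), vjp)


def _rows_scatter_add(idx, data, n_rows):
    """Unsorted scatter-add over axis 0 via a single bincount (much faster
    than np.add.at for our sizes)."""
    if data.ndim == 1:
        return np.bincount(idx, weights=data, minlength=n_rows).astype(_DTYPE)
    flat = data.reshape(len(idx), -1)
    d = flat.shape[1]
    comb = (idx[:, None] * d + np.arange(d)).ravel()
    out = np.bincount(comb, weights=flat.ravel(), minlength=n_rows * d)
    return out.astype(_DTYPE).reshape((n_rows,) + data.shape[1:])


def scatter(g, key, shape):
    """Adjoint of :func:`take`: place ``g`` at ``key`` inside zeros(shape)."""
    g = _as_tensor(g)

    def vjp(gg):
        return (take(gg, key),)

    if isinstance(key, np.ndarray) and key.ndim == 1:
        out = _rows_scatter_add(key, g.data, shape[0]).reshape(shape)
    else:
        out = np.zeros(shape)
        if isinstance(key, np.ndarray):
            np.add.at(out, key, g.data)
        else:
            out[key] = g.data
    return _make(out, (g,), vjp)


def segment_sum(x, idx, num_segments):
    """Sum rows of ``x`` into ``num_segments`` bins given by integer ``idx``."""
    x = _as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)

    def vjp(g):
        return (take(g, idx),)

    out = _rows_scatter_add(idx, x.data, num_segments)
    return _make(out, (x,), vjp)


def concatenate(parts, axis=0):
    parts = [_as_tensor(p) for p in parts]
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for k in range(len(parts)):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
            grads.append(take(g, tuple(key)))
        return tuple(grads)

    return _make(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), vjp)


# ---- einsum ---------------------------------------------------------------

def einsum(subscripts, *operands):
    """Restricted einsum: explicit ``->``, no ellipsis, no repeated index
    within a single operand.  Sufficient for tensor products, channel mixing
    and batched contractions; the vector-Jacobian product of each operand is
    itself an einsum, so the operation is infinitely differentiable.
    """
    if "->" not in subscripts or "..." in subscripts:
        raise ValueError("einsum requires explicit '->' and no ellipsis")
    lhs, out_sub = subscripts.split("->")
    in_subs = lhs.split(",")
    if len(in_subs) != len(operands):
        raise ValueError("operand count mismatch")
    for s in in_subs:
        if len(set(s)) != len(s):
            raise ValueError(f"repeated index within one operand: {s!r}")
    ops = [_as_tensor(o) for o in operands]
    dims = {}
    for s, o in zip(in_subs, ops):
        for ch, d in zip(s, o.shape):
            if dims.setdefault(ch, d) != d:
                raise ValueError(f"inconsistent dimension for index {ch!r}")

    def vjp(g):
        grads = []
        for k in range(len(ops)):
            if not ops[k].requires_grad:
                grads.append(None)
                continue
            subs = [out_sub] + [in_subs[j] for j in range(len(ops)) if j != k]
            args = [g] + [ops[j] for j in range(len(ops)) if j != k]
            have = set("".join(subs))
            for ch in in_subs[k]:
                if ch not in have:
                    subs.append(ch)
                    args.append(Tensor(np.ones(dims[ch])))
            grads.append(einsum(",".join(subs) + "->" + in_subs[k], *args))
        return tuple(grads)

    arrays = [o.data for o in ops]
    key = (subscripts, tuple(a.shape for a in arrays))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *arrays, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    out = np.einsum(subscripts, *arrays, optimize=path)
    return _make(out, tuple(ops), vjp)


_EINSUM_PATHS: dict = {}


# ---- elementwise nonlinear ------------------------------------------------

def sin(a):
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, cos(a)),)

    return _make(np.sin(a.data), (a,), vjp)


def cos(a):
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, mul(sin(a), -1.0)),)

    return _make(np.cos(a.data), (a,), vjp)


def exp(a):
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, out),)

    out = _make(np.exp(a.data), (a,), vjp)
    return out


def tanh(a):
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, add(1.0, mul(mul(out, out), -1.0))),)

    out = _make(np.tanh(a.data), (a,), vjp)
    return out


def sqrt(a):
    return power(a, 0.5)


def sigmoid(a):
    a = _as_tensor(a)

    def vjp(g):
        # reuse the forward output; it lives in the graph, so second-order
        # gradients remain exact
        return (mul(g, mul(out, add(1.0, mul(out, -1.0)))),)

    with np.errstate(over="ignore"):
        data = 1.0 / (1.0 + np.exp(-a.data))
    out = _make(data, (a,), vjp)
    return out


def silu(a):
    return mul(a, sigmoid(a))


def where(cond, a, b):
    """Elementwise select with a non-differentiable boolean condition."""
    cond = np.asarray(cond, dtype=bool)
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        zero = Tensor(np.zeros(g.shape))
        return (
            _unbroadcast(where(cond, g, zero), a.shape),
            _unbroadcast(where(cond, zero, g), b.shape),
        )

    return _make(np.where(cond, a.data, b.data), (a, b), vjp)


# ---- backward -------------------------------------------------------------

def _toposort(root):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    return order  # children appear after their parents


def grad(output, inputs, grad_output=None, create_graph=False):
    """Gradients of ``output`` w.r.t. each tensor in ``inputs``.

    ``output`` must be scalar unless ``grad_output`` is supplied.  With
    ``create_graph=True`` the returned gradients carry their own graph and can
    be differentiated again.
    """
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    if grad_output is None:
        if output.size != 1:
            raise ValueError("grad of non-scalar output needs grad_output")
        grad_output = Tensor(np.ones(output.shape))
    accum = {id(output): grad_output}
    order = _toposort(output)

    def run():
        for node in reversed(order):
            g = accum.pop(id(node), None)
            if g is None:
                continue
            node_grads[id(node)] = g
            if node.vjp is None:
                continue
            for parent, pg in zip(node.parents, node.vjp(g)):
                if not parent.requires_grad or pg is None:
                    continue
                prev = accum.get(id(parent))
                accum[id(parent)] = pg if prev is None else add(prev, pg)

    node_grads = {}
    if create_graph:
        run()
    else:
        with no_grad():
            run()
    out = []
    for t in inputs:
        g = node_grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape))
        out.append(g)
    return out[0] if single else out
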
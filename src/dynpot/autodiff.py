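"""Minimal reverse-mode automatic differentiation on numpy arrays.

Dynamic-training of a potential needs gradients of a *force*-dependent loss
with respect to network parameters.  Since forces are themselves gradients of
the predicted energy, the training gradient involves differentiating through
a backward pass (mixed second derivatives of the energy).  This module
provides exactly the machinery required for that and nothing more: a
:class:`Tensor` wrapping a float64 ndarray, a small set of primitive
operations whose vector-Jacobian products are expressed *in terms of the same
primitives*, and a functional :func:`grad` with a ``create_graph`` switch so
that gradients are themselves differentiable.

Conventions
-----------
* All data is float64.  Shapes are static once a tensor is built.
* Gradients are never stored on tensors; :func:`grad` returns them.
* With ``create_graph=False`` the backward pass runs inside :class:`no_grad`,
  producing constant tensors (cheap, non-differentiable result).
"""

from __future__ import annotations

import math
from contextlib import nullcontext
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "constant",
    "no_grad",
    "grad",
    "add",
    "mul",
    "matmul",
    "power",
    "tsum",
    "sin",
    "cos",
    "exp",
    "log",
    "absolute",
    "sqrt",
    "sigmoid",
    "silu",
    "tanh",
    "affine",
    "reshape",
    "transpose",
    "broadcast_to",
    "concat",
    "narrow",
    "gather",
    "scatter_add",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction."""

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

    # make numpy defer binary ops to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents: tuple = ()
        self.vjp: Callable | None = None
        self.requires_grad = bool(requires_grad)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other, dtype=np.float64))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)


def tensor(data) -> Tensor:
    return data if isinstance(data, Tensor) else Tensor(data)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def _make(data, parents: Sequence[Tensor], vjp: Callable) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.parents = tuple(parents)
        out.vjp = vjp
        out.requires_grad = True
    return out


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    ndiff = g.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    ash, bsh = a.shape, b.shape
    return _make(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, ash), _unbroadcast(g, bsh)),
    )


def mul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    ash, bsh = a.shape, b.shape
    return _make(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), ash), _unbroadcast(mul(g, a), bsh)),
    )


def power(a, p: float) -> Tensor:
    a = tensor(a)
    p = float(p)
    return _make(
        a.data ** p,
        (a,),
        lambda g: (mul(g, mul(power(a, p - 1.0), p)),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def matmul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    return _make(
        a.data @ b.data,
        (a, b),
        lambda g: (matmul(g, transpose(b)), matmul(transpose(a), g)),
    )


def transpose(a) -> Tensor:
    a = tensor(a)
    return _make(a.data.T, (a,), lambda g: (transpose(g),))


def affine(x, w, b) -> Tensor:
    """Fused x @ w + b (b broadcast over rows)."""
    x, w, b = tensor(x), tensor(w), tensor(b)
    return _make(
        x.data @ w.data + b.data,
        (x, w, b),
        lambda g: (matmul(g, transpose(w)), matmul(transpose(x), g), tsum(g, axis=0)),
    )


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    """Sum over ``axis`` (named ``tsum`` to avoid shadowing builtin ``sum``)."""
    a = tensor(a)
    in_shape = a.shape
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    kd_shape = tuple(1 if i in axes else n for i, n in enumerate(in_shape))

    def vjp(g):
        if g.shape != kd_shape:
            g = reshape(g, kd_shape)
        return (broadcast_to(g, in_shape),)

    return _make(a.data.sum(axis=axis if axis is None else axes, keepdims=keepdims), (a,), vjp)


def broadcast_to(a, shape) -> Tensor:
    a = tensor(a)
    in_shape = a.shape
    return _make(
        np.broadcast_to(a.data, shape),
        (a,),
        lambda g: (_unbroadcast(g, in_shape),),
    )


def reshape(a, shape) -> Tensor:
    a = tensor(a)
    in_shape = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, in_shape),))


def sin(a) -> Tensor:
    a = tensor(a)
    return _make(np.sin(a.data), (a,), lambda g: (mul(g, cos(a)),))


def cos(a) -> Tensor:
    a = tensor(a)
    return _make(np.cos(a.data), (a,), lambda g: (mul(g, mul(sin(a), -1.0)),))


def exp(a) -> Tensor:
    a = tensor(a)
    return _make(np.exp(a.data), (a,), lambda g: (mul(g, exp(a)),))


def log(a) -> Tensor:
    a = tensor(a)
    return _make(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def absolute(a) -> Tensor:
    # subgradient 0 at the origin; second derivative treated as zero
    a = tensor(a)
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (a,), lambda g: (mul(g, sign),))


def sigmoid(a) -> Tensor:
    a = tensor(a)
    with np.errstate(over="ignore"):
        s_data = np.where(
            a.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(a.data, 0, None))),
            np.exp(np.clip(a.data, None, 0)) / (1.0 + np.exp(np.clip(a.data, None, 0))),
        )
    out = _make(s_data, (a,), None)
    if out.requires_grad:
        # s' = s (1 - s), expressed via the output node so it stays differentiable
        out.vjp = lambda g: (mul(g, mul(out, add(mul(out, -1.0), 1.0))),)
    return out


def silu(a) -> Tensor:
    """x * sigmoid(x): smooth (C-infinity), as required for force training."""
    a = tensor(a)
    return mul(a, sigmoid(a))


def tanh(a) -> Tensor:
    a = tensor(a)
    e2 = exp(mul(a, 2.0))
    return mul(add(e2, -1.0), power(add(e2, 1.0), -1.0))


def concat(tensors: Sequence, axis: int = 0) -> Tensor:
    ts = [tensor(t) for t in tensors]
    axis = axis % ts[0].ndim
    sizes = [t.shape[axis] for t in ts]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        return tuple(narrow(g, axis, int(offsets[i]), sizes[i]) for i in range(len(ts)))

    return _make(np.concatenate([t.data for t in ts], axis=axis), ts, vjp)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = tensor(a)
    axis = axis % a.ndim
    total = a.shape[axis]
    idx = tuple(
        slice(start, start + length) if i == axis else slice(None) for i in range(a.ndim)
    )
    return _make(
        a.data[idx],
        (a,),
        lambda g: (_pad_zeros(g, axis, start, total),),
    )


def _pad_zeros(a, axis: int, start: int, total: int) -> Tensor:
    a = tensor(a)
    length = a.shape[axis]

    def fwd(data):
        shape = list(data.shape)
        shape[axis] = total
        out = np.zeros(shape)
        idx = tuple(
            slice(start, start + length) if i == axis else slice(None)
            for i in range(len(shape))
        )
        out[idx] = data
        return out

    return _make(fwd(a.data), (a,), lambda g: (narrow(g, axis, start, length),))


def gather(a, index: np.ndarray) -> Tensor:
    """Row gather along axis 0: out[k] = a[index[k]]."""
    a = tensor(a)
    index = np.asarray(index, dtype=np.intp)
    n = a.shape[0]
    return _make(a.data[index], (a,), lambda g: (scatter_add(g, index, n),))


def scatter_add(src, index: np.ndarray, num_rows: int) -> Tensor:
    """Segment sum along axis 0: out[i] = sum over k with index[k]==i of src[k]."""
    src = tensor(src)
    index = np.asarray(index, dtype=np.intp)

    def fwd(data):
        if data.ndim == 2:  # bincount is much faster than np.add.at here
            out = np.empty((num_rows, data.shape[1]))
            for j in range(data.shape[1]):
                out[:, j] = np.bincount(index, weights=data[:, j], minlength=num_rows)
            return out
        out = np.zeros((num_rows,) + data.shape[1:])
        np.add.at(out, index, data)
        return out

    return _make(fwd(src.data), (src,), lambda g: (gather(g, index),))


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    grad_output: Tensor | None = None,
    create_graph: bool = False,
    allow_unused: bool = False,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors are themselves
    differentiable (needed to optimise losses that depend on forces).
    """
    single = isinstance(inputs, Tensor)
    if single:
        inputs = [inputs]
    if not output.requires_grad:
        raise ValueError("output does not require grad; nothing to differentiate")

    # reverse post-order DFS = topological order over the DAG
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in visited:
                stack.append((p, False))

    grads: dict[int, Tensor] = {}
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape))
    grads[id(output)] = tensor(grad_output)

    ctx = nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None or node.vjp is None:
                continue
            for p, pg in zip(node.parents, node.vjp(g)):
                if pg is None or not p.requires_grad:
                    continue
                prev = grads.get(id(p))
                grads[id(p)] = pg if prev is None else add(prev, pg)

    result = []
    for inp in inputs:
        g = grads.get(id(inp))
        if g is None:
            if not allow_unused:
                raise ValueError("an input is not part of the graph of output")
            g = Tensor(np.zeros(inp.shape))
        result.append(g)
    return result[0] if single else result
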
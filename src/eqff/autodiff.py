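"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package computes forces as exact gradients of the potential energy and
trains with force-matching losses, which requires gradients *of* gradients
(the loss depends on dE/dR, and its optimization needs d(loss)/d(params)).
Every primitive therefore expresses its vector-Jacobian product in terms of
the same primitives, so the backward pass extends the computation graph and
can itself be differentiated (double backward), in the style of
HIPS/autograd.

Only the primitives the package needs are implemented; all data is float64.
Index arrays, boolean masks and shapes are plain numpy objects and are
treated as constants of the graph.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

__all__ = [
    "Tensor", "astensor", "constant", "grad",
    "add", "mul", "power", "exp", "log", "sin", "cos", "tanh", "erfc",
    "tsum", "broadcast_to", "reshape", "transpose", "concatenate",
    "narrow", "take", "scatter_add", "segment_sum", "einsum", "where",
    "sigmoid", "softplus", "silu", "relu_smooth", "norm",
]


class Tensor:
    """A node of the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents")

    def __init__(self, data, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents  # tuple of (Tensor, vjp) pairs

    # -- conveniences -------------------------------------------------
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

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, constant(-1.0))

    def __sub__(self, other):
        return add(self, -astensor(other))

    def __rsub__(self, other):
        return add(astensor(other), -self)

    def __mul__(self, other):
        return mul(self, astensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, n):
        return power(self, n)

    def __getitem__(self, idx):
        if isinstance(idx, (int, np.integer)):
            idx = np.asarray([idx])
            return reshape(take(self, idx, axis=0), self.data.shape[1:])
        if isinstance(idx, np.ndarray):
            return take(self, idx, axis=0)
        raise TypeError("Tensor indexing supports int or integer arrays only")


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    """A leaf tensor holding constants (no parents)."""
    return Tensor(np.asarray(x, dtype=np.float64))


def detach(x: Tensor) -> Tensor:
    """Cut the graph: same values, treated as a constant."""
    return constant(x.data.copy())


# ---------------------------------------------------------------------------
# broadcasting helper (built from primitives so it stays differentiable)

def _unbroadcast(g: Tensor, shape) -> Tensor:
    if g.data.shape == tuple(shape):
        return g
    ndiff = g.data.ndim - len(shape)
    if ndiff > 0:
        g = tsum(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic primitives

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data + b.data,
        (
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    return Tensor(
        a.data * b.data,
        (
            (a, lambda g: _unbroadcast(mul(g, b), a.data.shape)),
            (b, lambda g: _unbroadcast(mul(g, a), b.data.shape)),
        ),
    )


def power(a: Tensor, n: float) -> Tensor:
    """Elementwise a**n for a constant real exponent."""
    a = astensor(a)
    n = float(n)
    out = Tensor(a.data ** n)
    out.parents = ((a, lambda g: mul(g, mul(constant(n), power(a, n - 1.0)))),)
    return out


def exp(a: Tensor) -> Tensor:
    a = astensor(a)
    out = Tensor(np.exp(a.data))
    out.parents = ((a, lambda g: mul(g, out)),)
    return out


def log(a: Tensor) -> Tensor:
    a = astensor(a)
    return Tensor(np.log(a.data), ((a, lambda g: mul(g, power(a, -1.0))),))


def sin(a: Tensor) -> Tensor:
    a = astensor(a)
    return Tensor(np.sin(a.data), ((a, lambda g: mul(g, cos(a))),))


def cos(a: Tensor) -> Tensor:
    a = astensor(a)
    return Tensor(np.cos(a.data), ((a, lambda g: mul(g, -sin(a))),))


def tanh(a: Tensor) -> Tensor:
    a = astensor(a)
    out = Tensor(np.tanh(a.data))
    out.parents = ((a, lambda g: mul(g, add(constant(1.0), -mul(out, out)))),)
    return out


_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def erfc(a: Tensor) -> Tensor:
    a = astensor(a)
    return Tensor(
        _special.erfc(a.data),
        ((a, lambda g: mul(g, mul(constant(-_TWO_OVER_SQRT_PI), exp(-mul(a, a))))),),
    )


# ---------------------------------------------------------------------------
# shape primitives

def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    shape = a.data.shape

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(shape)), shape)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        axes = tuple(ax % len(shape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(shape))
            g = reshape(g, kshape)
        return broadcast_to(g, shape)

    return Tensor(np.sum(a.data, axis=axis, keepdims=keepdims), ((a, vjp),))


def broadcast_to(a: Tensor, shape) -> Tensor:
    a = astensor(a)
    return Tensor(
        np.broadcast_to(a.data, shape),
        ((a, lambda g: _unbroadcast(g, a.data.shape)),),
    )


def reshape(a: Tensor, shape) -> Tensor:
    a = astensor(a)
    old = a.data.shape
    return Tensor(a.data.reshape(shape), ((a, lambda g: reshape(g, old)),))


def transpose(a: Tensor, axes) -> Tensor:
    a = astensor(a)
    inv = tuple(np.argsort(axes))
    return Tensor(np.transpose(a.data, axes), ((a, lambda g: transpose(g, inv)),))


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    starts = np.concatenate([[0], np.cumsum(sizes)])
    parents = []
    for t, s0, n in zip(tensors, starts[:-1], sizes):
        parents.append((t, lambda g, s0=int(s0), n=int(n): narrow(g, axis, s0, n)))
    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(parents))


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    a = astensor(a)
    total = a.data.shape[axis]
    sl = tuple(
        slice(start, start + length) if i == axis else slice(None)
        for i in range(a.data.ndim)
    )
    return Tensor(
        a.data[sl], ((a, lambda g: _pad_zeros(g, axis, start, total)),)
    )


def _pad_zeros(a: Tensor, axis: int, start: int, total: int) -> Tensor:
    a = astensor(a)
    length = a.data.shape[axis]
    pad = [(0, 0)] * a.data.ndim
    pad[axis] = (start, total - start - length)
    return Tensor(
        np.pad(a.data, pad), ((a, lambda g: narrow(g, axis, start, length)),)
    )


# ---------------------------------------------------------------------------
# gather / scatter primitives (mutually inverse VJPs)

def take(a: Tensor, idx, axis: int = 0) -> Tensor:
    a = astensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    shape = a.data.shape
    return Tensor(
        np.take(a.data, idx, axis=axis),
        ((a, lambda g: scatter_add(g, idx, shape, axis)),),
    )


def scatter_add(v: Tensor, idx, shape, axis: int = 0) -> Tensor:
    """Zeros of `shape` with rows of `v` added at `idx` along `axis`."""
    v = astensor(v)
    idx = np.asarray(idx, dtype=np.intp)
    out = np.zeros(shape, dtype=np.float64)
    key = tuple(slice(None) if i != axis else idx for i in range(len(shape)))
    np.add.at(out, key, v.data)
    return Tensor(out, ((v, lambda g: take(g, idx, axis)),))


def segment_sum(v: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of v into num_segments bins along axis 0."""
    v = astensor(v)
    shape = (num_segments,) + v.data.shape[1:]
    return scatter_add(v, segment_ids, shape, axis=0)


# ---------------------------------------------------------------------------
# einsum

def einsum(spec: str, *operands) -> Tensor:
    """Differentiable einsum.

    Restriction (asserted): every index of each operand must appear in the
    output or in another operand, so the VJP is again an einsum.
    """
    operands = [astensor(op) for op in operands]
    lhs, out_sub = spec.replace(" ", "").split("->")
    subs = lhs.split(",")
    assert len(subs) == len(operands)
    for i, s in enumerate(subs):
        others = set(out_sub) | set("".join(subs[:i] + subs[i + 1:]))
        assert set(s) <= others, f"einsum spec {spec!r} not VJP-closed"
        assert len(set(s)) == len(s), "repeated index within one operand"

    parents = []
    for i, (s, op) in enumerate(zip(subs, operands)):
        other_subs = [out_sub] + [subs[j] for j in range(len(subs)) if j != i]
        other_ops_idx = [j for j in range(len(subs)) if j != i]
        new_spec = ",".join(other_subs) + "->" + s

        def vjp(g, new_spec=new_spec, other_ops_idx=tuple(other_ops_idx)):
            return einsum(new_spec, g, *[operands[j] for j in other_ops_idx])

        parents.append((op, vjp))
    return Tensor(np.einsum(spec, *[op.data for op in operands]), tuple(parents))


# ---------------------------------------------------------------------------
# piecewise / composite helpers

def where(mask, a: Tensor, b: Tensor) -> Tensor:
    """Select a where mask else b; mask is a constant boolean array."""
    m = constant(np.asarray(mask, dtype=np.float64))
    return add(mul(m, astensor(a)), mul(add(constant(1.0), -m), astensor(b)))


def sigmoid(a: Tensor) -> Tensor:
    """Numerically stable logistic function."""
    a = astensor(a)
    pos = a.data >= 0
    e = exp(-absval(a))
    s = power(add(constant(1.0), e), -1.0)  # 1/(1+e^-|a|)
    return where(pos, s, add(constant(1.0), -s))


def absval(a: Tensor) -> Tensor:
    a = astensor(a)
    sign = np.where(np.sign(a.data) == 0, 1.0, np.sign(a.data))
    return mul(constant(sign), a)


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(a)), stable for large |a|."""
    a = astensor(a)
    pos_part = where(a.data > 0, a, constant(np.zeros(a.data.shape)))
    return add(pos_part, log(add(constant(1.0), exp(-absval(a)))))


def silu(a: Tensor) -> Tensor:
    return mul(a, sigmoid(a))


def relu_smooth(a: Tensor, width: float = 0.05) -> Tensor:
    """C1 smoothed hinge: 0 for a <= -w, a for a >= w, quadratic between.

    Exactly zero below -width (unlike softplus), which keeps the valence
    correction inactive for well-behaved charges.
    """
    a = astensor(a)
    w = float(width)
    quad = mul(constant(1.0 / (4.0 * w)), power(add(a, constant(w)), 2.0))
    mid = where(a.data >= w, a, quad)
    return where(a.data <= -w, constant(np.zeros(a.data.shape)), mid)


def norm(a: Tensor, axis=-1) -> Tensor:
    return power(tsum(mul(a, a), axis=axis), 0.5)


# ---------------------------------------------------------------------------
# reverse-mode driver

def grad(output: Tensor, wrt, output_grad=None):
    """Gradients of `output` w.r.t. each tensor in `wrt`.

    Returns Tensors living on the (extended) graph so they can be
    differentiated again. Unreachable inputs get zero gradients.
    """
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)
    if output_grad is None:
        if output.data.size != 1:
            raise ValueError("grad of non-scalar output needs output_grad")
        output_grad = constant(np.ones_like(output.data))

    # nodes from which some wrt tensor is reachable
    wrt_ids = {id(t) for t in wrt_list}
    needed: dict[int, bool] = {}

    # iterative postorder DFS (graphs can be deep; reversed postorder is a
    # topological order of the DAG)
    stack = [(output, 0)]
    order: list[Tensor] = []
    visited: dict[int, int] = {}
    while stack:
        node, state = stack.pop()
        nid = id(node)
        if state == 0:
            if visited.get(nid):
                continue
            visited[nid] = 1
            stack.append((node, 1))
            for p, _ in node.parents:
                if not visited.get(id(p)):
                    stack.append((p, 0))
        else:
            order.append(node)
    # mark needed bottom-up
    for node in order:
        nid = id(node)
        needed[nid] = nid in wrt_ids or any(
            needed.get(id(p), False) for p, _ in node.parents
        )

    if not needed.get(id(output), False):
        zeros = [constant(np.zeros_like(t.data)) for t in wrt_list]
        return zeros[0] if single else zeros

    # reverse topological accumulation
    cotangent: dict[int, Tensor] = {id(output): output_grad}
    for node in reversed(order):
        nid = id(node)
        if nid not in cotangent or not needed.get(nid, False):
            continue
        g = cotangent[nid]
        for parent, vjp in node.parents:
            if not needed.get(id(parent), False):
                continue
            contrib = vjp(g)
            pid = id(parent)
            if pid in cotangent:
                cotangent[pid] = add(cotangent[pid], contrib)
            else:
                cotangent[pid] = contrib
    results = [
        cotangent.get(id(t), constant(np.zeros_like(t.data))) for t in wrt_list
    ]
    return results[0] if single else results
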
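"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run engine in the micrograd tradition, but operating on
``numpy.ndarray`` values and with one extra capability the rest of the package
depends on: vector-Jacobian products are themselves composed of primitive ops,
so gradients can be differentiated again (``create_graph=True``).  Second-order
gradients are required by the Wasserstein-GAN gradient penalty, whose value
depends on the gradient of the critic with respect to its input.

Everything is float64.  The engine is deliberately minimal: only the primitives
used by the layers in :mod:`clms.nn` exist, and no attempt is made at kernel
fusion or GPU execution — the package targets desk-scale experiments.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block (used by evaluation loops)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus (optionally) the graph node that produced it."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp = None

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return pow_const(self, p)

    def __matmul__(self, other):
        return einsum("ij,jk->ik", self, other)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    """Create an op output, recording the graph only when it can matter."""
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (reverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)), keepdims=False)
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape),
                            _unbroadcast(neg(g), b.shape)))


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data / b.data, (a, b),
                 lambda g: (_unbroadcast(div(g, b), a.shape),
                            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)))


def pow_const(a: Tensor, p: float) -> Tensor:
    p = float(p)
    return _node(a.data ** p, (a,),
                 lambda g: (mul(g, mul(Tensor(np.array(p)), pow_const(a, p - 1.0))),))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = _node(out_data, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    return pow_const(a, 0.5)


def tanh(a: Tensor) -> Tensor:
    out = _node(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, sub(Tensor(1.0), mul(out, out))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out = _node(1.0 / (1.0 + np.exp(-a.data)), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, sub(Tensor(1.0), out))),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    factor = Tensor(np.where(a.data > 0, 1.0, alpha))
    return _node(a.data * factor.data, (a,), lambda g: (mul(g, factor),))


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    in_shape = a.shape

    def vjp(g):
        gg = g
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            kshape = list(in_shape)
            for ax in axes:
                kshape[ax] = 1
            gg = reshape(gg, tuple(kshape))
        return (broadcast_to(gg, in_shape),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def mean_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis, keepdims), Tensor(1.0 / float(n)))


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (_unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    in_shape = a.shape
    return _node(a.data.reshape(shape), (a,),
                 lambda g: (reshape(g, in_shape),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,),
                 lambda g: (transpose(g, inv),))


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    ax = axis if axis >= 0 else tensors[0].ndim + axis
    sizes = [t.shape[ax] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        return tuple(slice_axis(g, int(offsets[i]), int(offsets[i + 1]), ax)
                     for i in range(len(tensors)))

    return _node(np.concatenate([t.data for t in tensors], axis=ax), tuple(tensors), vjp)


def slice_axis(a: Tensor, start: int, stop: int, axis: int = -1) -> Tensor:
    ax = axis if axis >= 0 else a.ndim + axis
    idx = tuple(slice(None) if i != ax else slice(start, stop) for i in range(a.ndim))
    in_len = a.shape[ax]

    def vjp(g):
        pad = [(0, 0)] * a.ndim
        pad[ax] = (start, in_len - stop)
        return (pad_axis(g, tuple(pad)),)

    return _node(a.data[idx], (a,), vjp)


def pad_axis(a: Tensor, pad_width: tuple) -> Tensor:
    """Zero-pad; ``pad_width`` is a full numpy-style per-axis tuple."""

    def vjp(g):
        idx = tuple(slice(l, g.shape[i] - r) for i, (l, r) in enumerate(pad_width))
        out = g
        for i, (l, r) in enumerate(pad_width):
            if l or r:
                out = slice_axis(out, l, out.shape[i] - r, axis=i)
        return (out,)

    return _node(np.pad(a.data, pad_width), (a,), vjp)


def pad_last(a: Tensor, left: int, right: int) -> Tensor:
    pw = tuple((0, 0) for _ in range(a.ndim - 1)) + ((left, right),)
    return pad_axis(a, pw)


def roll_last(a: Tensor, shift: int) -> Tensor:
    return _node(np.roll(a.data, shift, axis=-1), (a,),
                 lambda g: (roll_last(g, -shift),))


# ---------------------------------------------------------------------------
# einsum — the workhorse behind dense layers and convolutions
# ---------------------------------------------------------------------------

def einsum(spec: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum.

    Restriction (satisfied by every use in this package): every index of each
    operand must also appear in the output or in another operand, so each VJP
    is itself an einsum.
    """
    operands = tuple(_as_tensor(o) for o in operands)
    lhs, out_spec = spec.split("->")
    in_specs = lhs.split(",")

    def vjp(g):
        grads = []
        for i, ispec in enumerate(in_specs):
            others = [out_spec] + [s for j, s in enumerate(in_specs) if j != i]
            args = [g] + [o for j, o in enumerate(operands) if j != i]
            sub_spec = ",".join(others) + "->" + ispec
            grads.append(einsum(sub_spec, *args))
        return tuple(grads)

    return _node(np.einsum(spec, *[o.data for o in operands]), operands, vjp)


# ---------------------------------------------------------------------------
# sliding windows (conv1d support)
# ---------------------------------------------------------------------------

def unfold1d(a: Tensor, kernel: int, stride: int) -> Tensor:
    """(N, C, L) -> (N, C, L_out, K) sliding windows."""
    in_len = a.shape[-1]
    windows = np.lib.stride_tricks.sliding_window_view(a.data, kernel, axis=-1)
    out_data = np.ascontiguousarray(windows[..., ::stride, :])
    return _node(out_data, (a,),
                 lambda g: (fold1d(g, in_len, stride),))


def fold1d(a: Tensor, out_len: int, stride: int) -> Tensor:
    """Scatter-add windows back: (N, C, L_out, K) -> (N, C, out_len)."""
    n, c, l_out, k = a.shape

    def compute(data):
        res = np.zeros((n, c, out_len), dtype=np.float64)
        for j in range(k):  # k is a small kernel size
            pos = np.arange(l_out) * stride + j
            np.add.at(res, (slice(None), slice(None), pos), data[..., j])
        return res

    return _node(compute(a.data), (a,),
                 lambda g: (unfold1d(g, k, stride),))


# ---------------------------------------------------------------------------
# gather / scatter along the last axis (max-pool support)
# ---------------------------------------------------------------------------

def gather_last(a: Tensor, idx: np.ndarray) -> Tensor:
    """out[..., i] = a[..., idx[..., i]] with a fixed integer index array."""
    in_len = a.shape[-1]
    took = np.take_along_axis(a.data, idx, axis=-1)
    return _node(took, (a,), lambda g: (scatter_last(g, idx, in_len),))


def scatter_last(a: Tensor, idx: np.ndarray, out_len: int) -> Tensor:
    out_shape = a.shape[:-1] + (out_len,)

    def compute(data):
        res = np.zeros(out_shape, dtype=np.float64)
        np.put_along_axis(res, idx, 0.0, axis=-1)  # touch for shape safety
        flat_res = res.reshape(-1, out_len)
        flat_idx = idx.reshape(-1, idx.shape[-1])
        flat_dat = data.reshape(-1, data.shape[-1])
        rows = np.repeat(np.arange(flat_res.shape[0]), flat_idx.shape[1])
        np.add.at(flat_res, (rows, flat_idx.ravel()), flat_dat.ravel())
        return flat_res.reshape(out_shape)

    return _node(compute(a.data), (a,), lambda g: (gather_last(g, idx),))


def adaptive_max_pool1d(a: Tensor, out_len: int) -> Tensor:
    """Max-pool (N, C, L) to (N, C, out_len) with near-equal buckets.

    Bucket ``i`` covers [floor(i*L/out), ceil((i+1)*L/out)); realized as a
    gather at the per-bucket argmax so the gradient routes to the max element.
    """
    in_len = a.shape[-1]
    if out_len > in_len:
        raise ValueError(f"adaptive pool target {out_len} exceeds input length {in_len}")
    idx = np.empty(a.shape[:-1] + (out_len,), dtype=np.intp)
    for i in range(out_len):
        lo = (i * in_len) // out_len
        hi = -(-((i + 1) * in_len) // out_len)
        idx[..., i] = lo + np.argmax(a.data[..., lo:hi], axis=-1)
    return gather_last(a, idx)


# ---------------------------------------------------------------------------
# compositions
# ---------------------------------------------------------------------------

def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(sub(a, shift))
    return div(e, sum_(e, axis=axis, keepdims=True))


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    z = sub(a, shift)
    return sub(z, log(sum_(exp(z), axis=axis, keepdims=True)))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _topo(root: Tensor) -> list:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of a scalar (or seeded) output w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph and
    can be differentiated again.
    """
    global _GRAD_ENABLED
    inputs = list(inputs)
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads: dict[int, Tensor] = {id(output): _as_tensor(grad_output)}

    prev = _GRAD_ENABLED
    _GRAD_ENABLED = create_graph
    try:
        for node in reversed(_topo(output)):
            g = grads.pop(id(node), None)
            if g is None or node._vjp is None:
                if g is not None:
                    grads[id(node)] = g
                continue
            parent_grads = node._vjp(g)
            grads[id(node)] = g  # keep for inputs that are interior nodes
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
    finally:
        _GRAD_ENABLED = prev

    out = []
    for t in inputs:
        g = grads.get(id(t))
        out.append(g if g is not None else Tensor(np.zeros_like(t.data)))
    return out
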
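"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports higher-order derivatives: every vector-Jacobian product
(VJP) is itself expressed in terms of the ops defined here, so calling
:func:`grad` with ``create_graph=True`` yields gradients that are themselves
differentiable.  This is what makes the smoothed WGAN-GP penalty trainable —
its loss contains the gradient of the critic with respect to its input, and
updating the critic requires differentiating through that gradient.

Conventions
-----------
* Feature maps are NCHW ``(batch, channels, height, width)``.
* Ops never mutate their inputs; optimizers update leaf ``.data`` in place
  between graph constructions.
* ``max``-type ops route gradient to every argmax on ties (a measure-zero
  event for continuous data).
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def set_grad_enabled(mode: bool):
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = mode
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape node needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=dtype)
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, astensor(other, self))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, astensor(other, self))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(astensor(other, self)))

    def __rsub__(self, other):
        return add(astensor(other, self), neg(self))

    def __truediv__(self, other):
        return div(self, astensor(other, self))

    def __rtruediv__(self, other):
        return div(astensor(other, self), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, astensor(other, self))

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def astensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _node(data, parents, vjp) -> Tensor:
    """Build a result tensor, recording the tape node if grad is live."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (gs, ss) in enumerate(zip(g.shape, shape)) if ss == 1 and gs != 1
    )
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a: Tensor, b: Tensor) -> Tensor:
    def vjp(g):
        ga = _unbroadcast(div(g, b), a.shape)
        gb = _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)
        return ga, gb

    return _node(a.data / b.data, (a, b), vjp)


def power(a: Tensor, s: float) -> Tensor:
    s = float(s)
    return _node(a.data**s, (a,), lambda g: (mul(g, mul(power(a, s - 1.0), astensor(s, a))),))


def exp(a: Tensor) -> Tensor:
    out = _node(np.exp(a.data), (a,), None)
    out._vjp = (lambda g: (mul(g, out),)) if out.requires_grad else None
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a: Tensor) -> Tensor:
    out = _node(np.sqrt(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (div(g, mul(out, astensor(2.0, out))),)
    return out


def abs_(a: Tensor) -> Tensor:
    sign = Tensor(np.sign(a.data))
    return _node(np.abs(a.data), (a,), lambda g: (mul(g, sign),))


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = Tensor(np.where(a.data > 0, 1.0, slope).astype(a.dtype))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def sigmoid(a: Tensor) -> Tensor:
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)
    out = _node(out_data, (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, add(astensor(1.0, out), neg(out)))),)
    return out


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _node(
        np.reshape(a.data, shape),  # copies only when the layout requires it
        (a,),
        lambda g: (reshape(g, a.shape),),
    )


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _node(
        np.broadcast_to(a.data, shape),
        (a,),
        lambda g: (_unbroadcast(g, a.shape),),
    )


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            grads.append(getitem(g, tuple(idx)))
        return tuple(grads)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


def getitem(a: Tensor, idx) -> Tensor:
    return _node(a.data[idx], (a,), lambda g: (zeros_embed(g, idx, a.shape),))


def zeros_embed(g: Tensor, idx, shape) -> Tensor:
    """Adjoint of basic slicing: place ``g`` into a zero array of ``shape``."""
    data = np.zeros(shape, dtype=g.dtype)
    data[idx] = g.data
    return _node(data, (g,), lambda g2: (getitem(g2, idx),))


def pad_hw(a: Tensor, ph: int, pw: int) -> Tensor:
    """Zero-pad the last two (spatial) axes symmetrically."""
    if ph == 0 and pw == 0:
        return a
    n, c, h, w = a.shape
    idx = (slice(None), slice(None), slice(ph, ph + h), slice(pw, pw + w))
    data = np.pad(a.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    return _node(data, (a,), lambda g: (getitem(g, idx),))


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _axis_tuple(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(ax % ndim for ax in axis)


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = _axis_tuple(axis, a.ndim)
    kept = tuple(1 if i in axes else s for i, s in enumerate(a.shape))

    def vjp(g):
        return (broadcast_to(reshape(g, kept), a.shape),)

    return _node(a.data.sum(axis=axes, keepdims=keepdims), (a,), vjp)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = _axis_tuple(axis, a.ndim)
    count = int(np.prod([a.shape[i] for i in axes])) if axes else 1
    return mul(sum_(a, axis=axis, keepdims=keepdims), astensor(1.0 / count, a))


def max_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = _axis_tuple(axis, a.ndim)
    out_kept = a.data.max(axis=axes, keepdims=True)
    mask = Tensor((a.data == out_kept).astype(a.dtype))
    kept = out_kept.shape

    def vjp(g):
        return (mul(broadcast_to(reshape(g, kept), a.shape), mask),)

    data = out_kept if keepdims else out_kept.reshape(
        tuple(s for i, s in enumerate(a.shape) if i not in axes)
    )
    return _node(data, (a,), vjp)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def _swap_last(t: Tensor) -> Tensor:
    axes = tuple(range(t.ndim - 2)) + (t.ndim - 1, t.ndim - 2)
    return transpose(t, axes)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy's stacked-batch broadcasting on leading axes."""
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul operands must be at least 2-D")

    def vjp(g):
        ga = _unbroadcast(matmul(g, _swap_last(b)), a.shape)
        gb = _unbroadcast(matmul(_swap_last(a), g), b.shape)
        return ga, gb

    return _node(a.data @ b.data, (a, b), vjp)


# ---------------------------------------------------------------------------
# convolution plumbing
# ---------------------------------------------------------------------------

def im2col(a: Tensor, kh: int, kw: int, stride: int) -> Tensor:
    """Unfold NCHW into (N, C*kh*kw, OH*OW) patch columns (no padding here)."""
    n, c, h, w = a.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    v = np.lib.stride_tricks.sliding_window_view(a.data, (kh, kw), axis=(2, 3))
    v = v[:, :, ::stride, ::stride]  # (N,C,OH,OW,kh,kw)
    data = np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * kh * kw, oh * ow
    )
    return _node(data, (a,), lambda g: (col2im(g, kh, kw, stride, a.shape),))


def col2im(g: Tensor, kh: int, kw: int, stride: int, xshape) -> Tensor:
    """Adjoint of :func:`im2col`: scatter-add patch columns back."""
    n, c, h, w = xshape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    g6 = g.data.reshape(n, c, kh, kw, oh, ow)
    out = np.zeros(xshape, dtype=g.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += g6[
                :, :, i, j
            ]
    return _node(out, (g,), lambda g2: (im2col(g2, kh, kw, stride),))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, odd kernel, pad = k // 2.

    With this padding the output is H×W for stride 1 and ceil(H/2)×ceil(W/2)
    for stride 2 on even inputs.
    """
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    ph, pw = kh // 2, kw // 2
    oh = (h + 2 * ph - kh) // stride + 1
    ow = (wd + 2 * pw - kw) // stride + 1
    cols = im2col(pad_hw(x, ph, pw), kh, kw, stride)  # (N, K, L)
    k = c * kh * kw
    out = matmul(reshape(w, (o, k)), cols)  # (O,K) @ (N,K,L) -> (N,O,L)
    out = reshape(out, (n, o, oh, ow))
    if b is not None:
        out = add(out, reshape(b, (1, o, 1, 1)))
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2×2 stride-2 max pooling."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial size, got {h}x{w}")
    r = reshape(x, (n, c, h // 2, 2, w // 2, 2))
    return max_(r, axis=(3, 5))


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour ×2 upsampling of the spatial axes."""
    n, c, h, w = x.shape
    r = reshape(x, (n, c, h, 1, w, 1))
    return reshape(broadcast_to(r, (n, c, h, 2, w, 2)), (n, c, 2 * h, 2 * w))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def grad(output: Tensor, wrt, create_graph: bool = False, grad_output=None):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients carry their own tape
    and can be differentiated again (used by the gradient penalty).
    Tensors in ``wrt`` that the output does not depend on get ``None``.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(output, False)]
    while stack:
        t, processed = stack.pop()
        if processed:
            topo.append(t)
            continue
        if id(t) in seen or not t.requires_grad:
            continue
        seen.add(id(t))
        stack.append((t, True))
        for p in t._parents:
            stack.append((p, False))

    gmap: dict[int, Tensor] = {}
    seed = grad_output if grad_output is not None else Tensor(
        np.ones(output.shape, dtype=output.dtype)
    )
    gmap[id(output)] = seed
    with set_grad_enabled(create_graph):
        for t in reversed(topo):
            g = gmap.get(id(t))
            if g is None or t._vjp is None:
                continue
            for p, pg in zip(t._parents, t._vjp(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in gmap:
                    gmap[id(p)] = add(gmap[id(p)], pg)
                else:
                    gmap[id(p)] = pg
    return [gmap.get(id(w)) for w in wrt]
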
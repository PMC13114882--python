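"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
the closure that propagates incoming gradients to its parents.  Graphs are
built eagerly by the op functions below and traversed once, in reverse
topological order, by :meth:`Tensor.backward`.

Only the primitives needed by the transformer stack are implemented:
broadcasted add/mul, batched matmul, reshape/transpose/roll/concat,
softmax (with additive mask), layer norm, GELU, sigmoid, reductions and a
fused softmax cross-entropy.  Ops whose inputs all have
``requires_grad=False`` short-circuit to constant tensors so that inference
costs no tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "scale",
    "matmul",
    "reshape",
    "transpose",
    "roll",
    "concat",
    "mean",
    "sum_",
    "sigmoid",
    "relu",
    "gelu",
    "dropout",
    "layer_norm",
    "softmax",
    "softmax_cross_entropy",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "parents", "grad_fn", "decay")

    def __init__(self, data, requires_grad: bool = False, parents=(), grad_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.grad_fn = grad_fn
        # AdamW applies decoupled weight decay only where this is set (matrix weights).
        self.decay = False

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be a few thousand nodes deep)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node.grad_fn is not None:
                node.grad_fn(node.grad)

    def _accumulate(self, grad) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # conveniences used throughout the layers
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _make(data, parents, grad_fn) -> Tensor:
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=tuple(parents), grad_fn=grad_fn)
    return Tensor(data)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out = _make(out_data, (a, b), grad_fn)
    return out


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(-_unbroadcast(g, b.data.shape))

    return _make(a.data - b.data, (a, b), grad_fn)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), grad_fn)


def scale(a, c: float) -> Tensor:
    a = _as_tensor(a)

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return _make(a.data * c, (a,), grad_fn)


def matmul(a, b) -> Tensor:
    """Batched matrix product with numpy broadcasting on leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def grad_fn(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), grad_fn)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), grad_fn)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    inv = tuple(np.argsort(axes))

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), grad_fn)


def roll(a, shifts, axes) -> Tensor:
    a = _as_tensor(a)
    neg = tuple(-s for s in shifts)

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(np.roll(g, neg, axis=axes))

    return _make(np.roll(a.data, shifts, axis=axes), (a,), grad_fn)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, grad_fn)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )

    def grad_fn(g):
        if a.requires_grad:
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis=axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape) / n)

    return _make(out_data, (a,), grad_fn)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)

    def grad_fn(g):
        if a.requires_grad:
            gg = np.asarray(g)
            if not keepdims and axis is not None:
                gg = np.expand_dims(gg, axis=axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), grad_fn)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(g * y * (1.0 - y))

    return _make(y, (a,), grad_fn)


def dropout(a, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero with probability p, scale kept units by 1/(1-p)."""
    a = _as_tensor(a)
    keep = (rng.random(a.data.shape) >= p) / (1.0 - p)

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(g * keep)

    return _make(a.data * keep, (a,), grad_fn)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    pos = a.data > 0

    def grad_fn(g):
        if a.requires_grad:
            a._accumulate(g * pos)

    return _make(np.where(pos, a.data, 0.0), (a,), grad_fn)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(a) -> Tensor:
    """GELU, tanh approximation (exact derivative of the approximation)."""
    a = _as_tensor(a)
    x = a.data
    inner = _GELU_C * (x + 0.044715 * x**3)
    t = np.tanh(inner)
    y = 0.5 * x * (1.0 + t)

    def grad_fn(g):
        if a.requires_grad:
            dinner = _GELU_C * (1.0 + 3 * 0.044715 * x**2)
            dy = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            a._accumulate(g * dy)

    return _make(y, (a,), grad_fn)


def layer_norm(a, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    a, gamma, beta = _as_tensor(a), _as_tensor(gamma), _as_tensor(beta)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data
    n = a.data.shape[-1]

    def grad_fn(g):
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if a.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (
                (gx * xhat).mean(axis=-1, keepdims=True)
            )
            a._accumulate(term * inv)

    return _make(out_data, (a, gamma, beta), grad_fn)


def softmax(a, mask=None) -> Tensor:
    """Softmax over the last axis; ``mask`` is an additive numpy constant
    (0 where allowed, ``-inf``/large-negative where disallowed)."""
    a = _as_tensor(a)
    x = a.data if mask is None else a.data + mask
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    y = e / e.sum(axis=-1, keepdims=True)

    def grad_fn(g):
        if a.requires_grad:
            dot = (g * y).sum(axis=-1, keepdims=True)
            a._accumulate(y * (g - dot))

    return _make(y, (a,), grad_fn)


def softmax_cross_entropy(logits, y_onehot) -> Tensor:
    """Mean over the batch of ``-sum_c y_c log softmax(z)_c``."""
    logits = _as_tensor(logits)
    y = np.asarray(y_onehot, dtype=np.float64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    batch = int(np.prod(logits.data.shape[:-1])) or 1
    loss = -(y * logp).sum() / batch

    def grad_fn(g):
        if logits.requires_grad:
            p = np.exp(logp)
            logits._accumulate(g * (p - y) / batch)

    return _make(loss, (logits,), grad_fn)
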
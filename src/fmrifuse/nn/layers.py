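"""Transformer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "trunc_normal",
    "Linear",
    "LayerNorm",
    "Mlp",
    "MultiheadSelfAttention",
    "TransformerBlock",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated to +-2 std (clipping form)."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


def Parameter(data, decay: bool = False) -> Tensor:
    p = Tensor(data, requires_grad=True)
    p.decay = decay
    return p


class Module:
    """Parameter container; recursively collects Tensors marked trainable."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return out

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, module has {len(params)} parameters"
            )
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {arr.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(trunc_normal(rng, (in_dim, out_dim)), decay=True)
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


class Mlp(Module):
    """Two-layer feed-forward block.  ReLU rather than GELU: on CPU the
    transcendental in GELU dominates the whole forward pass at these model
    sizes, and at depth <= 4 the choice is immaterial for optimization."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(x)))


class MultiheadSelfAttention(Module):
    """Softmax(QK^T/sqrt(d))V with ``heads`` parallel heads.

    ``mask`` is an additive numpy array broadcastable to the score shape
    ``[batch, heads, n, n]``.  When ``record`` is set, the post-softmax
    attention probabilities of the call are kept (detached) in
    ``last_attention`` for inspection and attribution.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.dropout = dropout
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 record: bool = False,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        b, n, d = x.shape
        h, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return ad.transpose(ad.reshape(t, (b, n, h, hd)), (0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = ad.scale(ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(hd))
        attn = ad.softmax(scores, mask=mask)
        if record:
            self.last_attention = attn.data.copy()
        if drop_rng is not None and self.dropout > 0:
            attn = ad.dropout(attn, self.dropout, drop_rng)
        out = ad.matmul(attn, v)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (b, n, d))
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm residual block: x + MSA(LN(x)); x + MLP(LN(x)).

    ``dropout`` (train-time only, activated by passing ``drop_rng``) applies
    to the attention probabilities and to each residual branch output —
    the classic transformer regularizer, which also discourages the model
    from concentrating all its reliance on a single token or path.
    """

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.dropout = dropout
        self.norm1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng, dropout=dropout)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(round(dim * mlp_ratio)), rng)

    def _maybe_drop(self, t: Tensor, drop_rng) -> Tensor:
        if drop_rng is not None and self.dropout > 0:
            return ad.dropout(t, self.dropout, drop_rng)
        return t

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 record: bool = False,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        x = x + self._maybe_drop(
            self.attn(self.norm1(x), mask=mask, record=record,
                      drop_rng=drop_rng), drop_rng)
        return x + self._maybe_drop(self.mlp(self.norm2(x)), drop_rng)
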
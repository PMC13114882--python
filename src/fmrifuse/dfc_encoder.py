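"""Transformer encoders for aligned dFC sequences, one per atlas.

Each connectivity frame of an aligned sequence ``[L, Na, Na]`` is cut into
non-overlapping ``P x P`` patches (the frame is zero-padded up to the next
multiple of ``P`` on the high side when ``P`` does not divide ``Na``); each
patch is flattened and projected by an atlas-specific linear map, giving
``L * ceil(Na/P)^2`` tokens ordered frame-major.  Learnable positional
embeddings are added and ``depth`` full-attention transformer blocks are
applied; the atlas embedding is the global average over final tokens.

``roi_token_mode`` replaces the patch tokenizer by one token per ROI per
frame (the projected ROI row of the frame).  This keeps attention and
features indexed by ROI, which is what the attention-based ROI attribution
requires; for classification the patch tokenizer is the default.

Atlas embeddings are fused by concatenation in a fixed atlas order followed
by a learnable linear map to the fused dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "DfcEncoderConfig",
    "tokenize_dfc",
    "n_dfc_tokens",
    "AtlasDfcEncoder",
    "AtlasFusion",
    "MultiAtlasDfcEncoder",
]


@dataclass
class DfcEncoderConfig:
    patch_size: int = 2
    embed_dim: int = 64
    depth: int = 2
    heads: int = 4
    fused_dim: int = 64
    roi_token_mode: bool = False
    mlp_ratio: float = 4.0
    dropout: float = 0.0
    #: train-time dropout on raw connectivity entries (denoising
    #: augmentation); because each inter-regional value appears in two
    #: symmetric rows, masking entries pushes the model to read both copies
    #: instead of collapsing onto one, which keeps ROI attribution faithful
    input_dropout: float = 0.0
    #: extra learned tokens appended to the sequence; transformers tend to
    #: repurpose low-information tokens as high-norm computation "registers",
    #: which corrupts norm-based token attribution — dedicated registers give
    #: that computation somewhere to live and are excluded from attribution
    n_registers: int = 0

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")


def n_dfc_tokens(L: int, n_rois: int, cfg: DfcEncoderConfig) -> int:
    """Token-count law: L * ceil(Na/P)^2 in patch mode, L * Na in ROI mode."""
    if cfg.roi_token_mode:
        return L * n_rois
    per_side = -(-n_rois // cfg.patch_size)
    return L * per_side * per_side


def tokenize_dfc(aligned: np.ndarray, cfg: DfcEncoderConfig) -> np.ndarray:
    """Flatten an aligned dFC batch into raw token vectors (pre-projection).

    ``aligned``: [B, L, Na, Na] (a leading batch axis is added if absent).
    Returns [B, n_tokens, P*P] (patch mode, patches row-major per frame,
    frames major) or [B, L*Na, Na] (ROI-token mode).
    """
    a = np.asarray(aligned, dtype=np.float64)
    if a.ndim == 3:
        a = a[None]
    b, L, na, _ = a.shape
    if cfg.roi_token_mode:
        return a.reshape(b, L * na, na)
    p = cfg.patch_size
    target = -(-na // p) * p
    if target != na:
        pad = target - na
        a = np.pad(a, ((0, 0), (0, 0), (0, pad), (0, pad)))
    m = target // p
    v = a.reshape(b, L, m, p, m, p)
    v = v.transpose(0, 1, 2, 4, 3, 5)  # [B, L, m, m, p, p]
    return v.reshape(b, L * m * m, p * p)


class AtlasDfcEncoder(nn.Module):
    """Atlas-specific tokenizer + transformer encoder + global average pool."""

    def __init__(self, atlas_id: str, n_rois: int, n_frames: int,
                 cfg: DfcEncoderConfig, rng: np.random.Generator):
        self.atlas_id = atlas_id
        self.n_rois = n_rois
        self.n_frames = n_frames
        self.cfg = cfg
        token_dim = n_rois if cfg.roi_token_mode else cfg.patch_size**2
        self.n_tokens = n_dfc_tokens(n_frames, n_rois, cfg)
        self.proj = nn.Linear(token_dim, cfg.embed_dim, rng)
        self.pos = nn.Parameter(nn.trunc_normal(rng, (self.n_tokens, cfg.embed_dim)))
        self.registers = (nn.Parameter(nn.trunc_normal(rng, (cfg.n_registers,
                                                             cfg.embed_dim)))
                          if cfg.n_registers else None)
        self.blocks = [
            nn.TransformerBlock(cfg.embed_dim, cfg.heads, cfg.mlp_ratio, rng,
                                dropout=cfg.dropout)
            for _ in range(cfg.depth)
        ]

    def encode_tokens(self, aligned: np.ndarray, record: bool = False,
                      drop_rng=None) -> Tensor:
        """Final-layer token sequence [B, n_tokens, Dd]."""
        raw = tokenize_dfc(aligned, self.cfg)
        if raw.shape[1] != self.n_tokens:
            raise ValueError(
                f"atlas {self.atlas_id}: got {raw.shape[1]} tokens, "
                f"encoder built for {self.n_tokens}"
            )
        tokens = Tensor(raw)
        if drop_rng is not None and self.cfg.input_dropout > 0:
            tokens = nn.dropout(tokens, self.cfg.input_dropout, drop_rng)
        h = self.proj(tokens) + self.pos
        if self.registers is not None:
            b = raw.shape[0]
            reg = nn.add(Tensor(np.zeros((b,) + self.registers.shape)),
                         self.registers)
            h = nn.concat([h, reg], axis=1)
        for i, blk in enumerate(self.blocks):
            h = blk(h, record=record and i == len(self.blocks) - 1,
                    drop_rng=drop_rng)
        return h

    def __call__(self, aligned: np.ndarray, record: bool = False,
                 drop_rng=None) -> Tensor:
        return nn.mean(self.encode_tokens(aligned, record=record,
                                          drop_rng=drop_rng), axis=1)

    def final_attention(self) -> np.ndarray:
        """Recorded last-block attention [B, heads, n_tokens, n_tokens]."""
        attn = self.blocks[-1].attn.last_attention
        if attn is None:
            raise RuntimeError("no attention recorded; call with record=True first")
        return attn


class AtlasFusion(nn.Module):
    """Concatenate atlas embeddings in fixed order, then a learnable linear map."""

    def __init__(self, atlas_order: list[str], embed_dim: int, fused_dim: int,
                 rng: np.random.Generator):
        self.atlas_order = list(atlas_order)
        self.fuse = nn.Linear(embed_dim * len(atlas_order), fused_dim, rng)

    def __call__(self, embeddings: dict[str, Tensor]) -> Tensor:
        unknown = set(embeddings) - set(self.atlas_order)
        if unknown:
            raise KeyError(f"unknown atlas id(s): {sorted(unknown)}")
        missing = [a for a in self.atlas_order if a not in embeddings]
        if missing:
            raise KeyError(f"missing atlas embedding(s): {missing}")
        return self.fuse(nn.concat([embeddings[a] for a in self.atlas_order], axis=-1))


class MultiAtlasDfcEncoder(nn.Module):
    """Per-atlas encoders (no shared parameters) plus cross-atlas fusion."""

    def __init__(self, atlas_rois: dict[str, int], n_frames: int,
                 cfg: DfcEncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.encoders = {
            atlas: AtlasDfcEncoder(atlas, na, n_frames, cfg, rng)
            for atlas, na in atlas_rois.items()
        }
        self.fusion = AtlasFusion(list(atlas_rois), cfg.embed_dim, cfg.fused_dim, rng)

    def __call__(self, bundle: dict[str, np.ndarray], record: bool = False,
                 drop_rng=None) -> Tensor:
        embeddings = {
            atlas: enc(bundle[atlas], record=record, drop_rng=drop_rng)
            for atlas, enc in self.encoders.items()
        }
        return self.fusion(embeddings)
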
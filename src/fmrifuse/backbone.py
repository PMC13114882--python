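"""4D spatiotemporal voxel encoder.

A BOLD clip ``[side, side, side, T]`` is cut into non-overlapping 4D
patches of size ``(pz, py, px) x pt``, linearly projected to ``D``-dim
tokens laid out row-major over the token grid ``(nz, ny, nx, nt)``, given a
learnable positional table, and passed through a stack of windowed
self-attention blocks.  Attention is restricted to local 4D windows;
odd-indexed blocks cyclically shift the grid by half a window per axis so
information crosses window boundaries, with token pairs that span the
cyclic wrap seam masked out.  The clip embedding is the mean over final
tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["BackboneConfig", "VoxelTransformer4D", "patch_grid"]

_NEG = -1e9  # additive mask value for disallowed attention pairs


@dataclass
class BackboneConfig:
    """Voxel-branch hyperparameters (token units for ``window_size``).

    The defaults are a small CPU-friendly configuration for 24^3 x 8 clips;
    the 96^3 x 20 acquisition-scale input is reached purely through config.
    """

    spatial_patch: tuple[int, int, int] = (8, 8, 8)
    temporal_patch: int = 2
    embed_dim: int = 64
    depth: int = 4
    heads: int = 4
    window_size: tuple[int, int, int, int] = (3, 3, 3, 2)
    shift_pattern: bool = True
    mlp_ratio: float = 4.0
    dropout: float = 0.0


def patch_grid(clip_shape: tuple[int, int, int, int],
               cfg: BackboneConfig) -> tuple[int, int, int, int]:
    """Token-grid shape; raises naming the offending axis on indivisibility."""
    sizes = list(clip_shape[:3]) + [clip_shape[3]]
    patches = list(cfg.spatial_patch) + [cfg.temporal_patch]
    names = "zyxt"
    grid = []
    for name, size, p in zip(names, sizes, patches):
        if size % p:
            raise ValueError(f"axis {name}: extent {size} not divisible by patch {p}")
        grid.append(size // p)
    return tuple(grid)


class _WindowedBlock(nn.Module):
    """One transformer block with (optionally shifted) 4D window attention."""

    def __init__(self, cfg: BackboneConfig, grid, shifted: bool,
                 rng: np.random.Generator):
        d = cfg.embed_dim
        self.grid = tuple(grid)
        self.window = tuple(cfg.window_size)
        for name, g, w in zip("zyxt", self.grid, self.window):
            if g % w:
                raise ValueError(f"axis {name}: grid {g} not divisible by window {w}")
        # no shift along axes the window already spans entirely
        self.shifts = tuple(
            (w // 2 if (shifted and w < g) else 0)
            for g, w in zip(self.grid, self.window)
        )
        self.block = nn.TransformerBlock(d, cfg.heads, cfg.mlp_ratio, rng,
                                         dropout=cfg.dropout)
        self.n_windows = int(np.prod([g // w for g, w in zip(self.grid, self.window)]))
        self.window_len = int(np.prod(self.window))
        self.mask = self._wrap_mask() if any(self.shifts) else None

    def _partition_ids(self, grid_vals: np.ndarray) -> np.ndarray:
        gz, gy, gx, gt = self.grid
        wz, wy, wx, wt = self.window
        v = grid_vals.reshape(gz // wz, wz, gy // wy, wy, gx // wx, wx, gt // wt, wt)
        v = v.transpose(0, 2, 4, 6, 1, 3, 5, 7)
        return v.reshape(self.n_windows, self.window_len)

    def _wrap_mask(self) -> np.ndarray:
        """Additive mask [n_windows, 1, wlen, wlen]: tokens on opposite sides
        of a cyclic wrap seam (per shifted axis) may not attend."""
        region = np.zeros(self.grid, dtype=np.int64)
        for axis, (g, s) in enumerate(zip(self.grid, self.shifts)):
            if s == 0:
                continue
            bit = (np.arange(g) >= g - s).astype(np.int64)
            shape = [1, 1, 1, 1]
            shape[axis] = g
            region = region * 2 + bit.reshape(shape)
        ids = self._partition_ids(region)
        same = ids[:, :, None] == ids[:, None, :]
        return np.where(same, 0.0, _NEG)[:, None, :, :]

    def __call__(self, x: Tensor, record: bool = False,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        b = x.shape[0]
        gz, gy, gx, gt = self.grid
        wz, wy, wx, wt = self.window
        d = x.shape[-1]

        def inner(h: Tensor) -> Tensor:
            h = nn.reshape(h, (b, gz, gy, gx, gt, d))
            if any(self.shifts):
                h = nn.roll(h, tuple(-s for s in self.shifts), (1, 2, 3, 4))
            h = nn.reshape(h, (b, gz // wz, wz, gy // wy, wy, gx // wx, wx,
                               gt // wt, wt, d))
            h = nn.transpose(h, (0, 1, 3, 5, 7, 2, 4, 6, 8, 9))
            h = nn.reshape(h, (b * self.n_windows, self.window_len, d))
            mask = None if self.mask is None else np.tile(self.mask, (b, 1, 1, 1))
            h = self.block.attn(self.block.norm1(h), mask=mask, record=record,
                                drop_rng=drop_rng)
            h = nn.reshape(h, (b, gz // wz, gy // wy, gx // wx, gt // wt,
                               wz, wy, wx, wt, d))
            h = nn.transpose(h, (0, 1, 5, 2, 6, 3, 7, 4, 8, 9))
            h = nn.reshape(h, (b, gz, gy, gx, gt, d))
            if any(self.shifts):
                h = nn.roll(h, self.shifts, (1, 2, 3, 4))
            return nn.reshape(h, (b, gz * gy * gx * gt, d))

        x = x + self.block._maybe_drop(inner(x), drop_rng)
        return x + self.block._maybe_drop(self.block.mlp(self.block.norm2(x)),
                                          drop_rng)


class VoxelTransformer4D(nn.Module):
    """Clip encoder: patchify -> +position -> windowed blocks -> mean pool."""

    def __init__(self, cfg: BackboneConfig, clip_shape: tuple[int, int, int, int],
                 rng: np.random.Generator):
        self.cfg = cfg
        self.clip_shape = tuple(clip_shape)
        self.grid = patch_grid(self.clip_shape, cfg)
        self.n_tokens = int(np.prod(self.grid))
        pz, py, px = cfg.spatial_patch
        self.patch_dim = pz * py * px * cfg.temporal_patch
        self.proj = nn.Linear(self.patch_dim, cfg.embed_dim, rng)
        self.pos = nn.Parameter(nn.trunc_normal(rng, (self.n_tokens, cfg.embed_dim)))
        self.blocks = [
            _WindowedBlock(cfg, self.grid, shifted=cfg.shift_pattern and (i % 2 == 1),
                           rng=rng)
            for i in range(cfg.depth)
        ]
        self.norm = nn.LayerNorm(cfg.embed_dim)  # final norm before pooling

    def patchify(self, clips: np.ndarray) -> np.ndarray:
        """[B, sz, sy, sx, T] -> flattened patch matrix [B, N, patch_dim]."""
        clips = np.asarray(clips, dtype=np.float64)
        if clips.shape[1:] != self.clip_shape:
            raise ValueError(f"clip shape {clips.shape[1:]} != {self.clip_shape}")
        nz, ny, nx, nt = self.grid
        pz, py, px = self.cfg.spatial_patch
        pt = self.cfg.temporal_patch
        b = clips.shape[0]
        v = clips.reshape(b, nz, pz, ny, py, nx, px, nt, pt)
        v = v.transpose(0, 1, 3, 5, 7, 2, 4, 6, 8)
        return v.reshape(b, self.n_tokens, self.patch_dim)

    def tokens(self, clips: np.ndarray) -> Tensor:
        """Projected patch tokens plus positional table, shape [B, N, D]."""
        h = self.proj(Tensor(self.patchify(clips)))
        return h + self.pos

    def __call__(self, clips: np.ndarray, record: bool = False,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        h = self.tokens(clips)
        for blk in self.blocks:
            h = blk(h, record=record, drop_rng=drop_rng)
        return nn.mean(self.norm(h), axis=1)  # [B, D]

    def load_pretrained(self, path) -> None:
        """Load externally trained backbone weights (.npz archive written by
        :meth:`save_weights`)."""
        with np.load(path) as f:
            self.load_state([f[k] for k in sorted(f.files, key=lambda s: int(s))])

    def save_weights(self, path) -> None:
        np.savez(path, **{str(i): p for i, p in enumerate(self.state_dict())})
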
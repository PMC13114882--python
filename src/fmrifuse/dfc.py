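"""Sliding-window dynamic functional connectivity (dFC).

A scan of ``Ts`` volumes with window length ``W`` and step ``S`` (both in
volumes) yields ``Ls = floor((Ts - W) / S) + 1`` windows; window ``k``
covers the half-open volume range ``[k*S, k*S + W)``.  With the reference
acquisition (TR = 2.0 s) a 60 s window and 4 s step give W = 30, S = 2.

Temporal alignment to a voxel clip starting at volume ``t0`` uses
``k0 = floor(t0 / S)`` for the start window and ``L = ceil(T * delta / S)``
for the aligned length: floor for the start and ceiling for the length are
the unique pair guaranteeing that the aligned windows' volume span covers
the clip span whenever no end-of-scan padding occurs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .io import RegionalTimeSeries

__all__ = [
    "DfcParams",
    "DfcSequence",
    "AlignedDfc",
    "window_indices",
    "windowed_correlation",
    "build_dfc_sequence",
    "align_dfc",
    "dfc_bundle",
    "aligned_length",
    "save_dfc_cache",
    "load_dfc_cache",
]


@dataclass(frozen=True)
class DfcParams:
    """Sliding-window parameters in volumes."""

    window_volumes: int = 30
    step_volumes: int = 2

    def __post_init__(self):
        if self.window_volumes < 2:
            raise ValueError("correlation needs a window of at least 2 volumes")
        if self.step_volumes < 1:
            raise ValueError("step must be at least 1 volume")

    @classmethod
    def from_seconds(cls, window_seconds: float, step_seconds: float,
                     tr_seconds: float) -> "DfcParams":
        return cls(
            window_volumes=int(round(window_seconds / tr_seconds)),
            step_volumes=int(round(step_seconds / tr_seconds)),
        )


@dataclass
class DfcSequence:
    """Stack of windowed correlation matrices, shape [Ls, Na, Na]."""

    data: np.ndarray
    atlas_id: str
    params: DfcParams

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class AlignedDfc:
    """Clip-aligned dFC subsequence [L, Na, Na]; trailing frames may be
    zero-padded when the scan ends before the clip's temporal span."""

    data: np.ndarray
    k0: int
    n_padded: int
    atlas_id: str = ""


def window_indices(ts: int, params: DfcParams) -> list[range]:
    """Half-open volume ranges of every full sliding window."""
    w, s = params.window_volumes, params.step_volumes
    if ts < w:
        raise ValueError(f"scan of {ts} volumes shorter than window {w}")
    n = (ts - w) // s + 1
    return [range(k * s, k * s + w) for k in range(n)]


def windowed_correlation(series: RegionalTimeSeries | np.ndarray,
                         window: range) -> np.ndarray:
    """Pearson correlation between ROI pairs within one window.

    Zero-variance ROIs get 0 off-diagonal and 1 on the diagonal, keeping the
    matrix finite ("no evidence of coupling").
    """
    values = series.values if isinstance(series, RegionalTimeSeries) else np.asarray(series)
    block = values[window.start: window.stop]
    if block.shape[0] < 2:
        raise ValueError("correlation window must contain at least 2 samples")
    x = block - block.mean(axis=0)
    sd = x.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"zero-variance ROI(s) {np.flatnonzero(flat)} in window {window}")
    sd_safe = np.where(flat, 1.0, sd)
    xn = x / sd_safe
    corr = xn.T @ xn / block.shape[0]
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def build_dfc_sequence(series: RegionalTimeSeries, params: DfcParams) -> DfcSequence:
    windows = window_indices(series.n_volumes, params)
    data = np.stack([windowed_correlation(series, w) for w in windows])
    return DfcSequence(data=data, atlas_id=series.atlas_id, params=params)


def aligned_length(T: int, delta: int, step_volumes: int) -> int:
    """Number of aligned windows covering a clip: ceil(T * delta / S)."""
    return -(-(T * delta) // step_volumes)


def align_dfc(seq: DfcSequence, t0: int, T: int, delta: int = 1,
              L_override: int | None = None) -> AlignedDfc:
    """Extract the clip-aligned subsequence, zero-padding past scan end.

    ``L_override``, when given, wins over the coverage-matching length and
    is logged, since both are defined knobs.
    """
    if t0 < 0:
        raise ValueError("t0 must be non-negative")
    s = seq.params.step_volumes
    k0 = t0 // s
    L = L_override if L_override is not None else aligned_length(T, delta, s)
    if L_override is not None:
        warnings.warn(f"L_override={L_override} supersedes coverage length "
                      f"{aligned_length(T, delta, s)}")
    ls, na = seq.n_windows, seq.n_rois
    out = np.zeros((L, na, na), dtype=seq.data.dtype)
    n_copied = max(0, min(k0 + L, ls) - k0)
    if n_copied == 0:
        warnings.warn(f"clip start window k0={k0} beyond last window {ls - 1}; "
                      "aligned sequence is fully zero-padded")
    else:
        out[:n_copied] = seq.data[k0: k0 + n_copied]
    return AlignedDfc(data=out, k0=k0, n_padded=L - n_copied, atlas_id=seq.atlas_id)


def dfc_bundle(sequences: dict[str, DfcSequence], t0: int, T: int,
               delta: int = 1, L_override: int | None = None,
               atlases: list[str] | None = None) -> dict[str, AlignedDfc]:
    """One aligned dFC per atlas, all sharing the same k0/L derivation."""
    atlases = atlases if atlases is not None else list(sequences)
    missing = [a for a in atlases if a not in sequences]
    if missing:
        raise KeyError(f"missing dFC sequence for atlas(es): {missing}")
    steps = {sequences[a].params.step_volumes for a in atlases}
    if len(steps) > 1:
        raise ValueError(f"atlases disagree on step size: {steps}")
    return {a: align_dfc(sequences[a], t0, T, delta, L_override) for a in atlases}


def save_dfc_cache(path, subject_id: str, seq: DfcSequence, tr_seconds: float,
                   ts: int) -> None:
    """Cache a dFC sequence under /<subject>/<atlas>/dfc with W, S, TR, Ts attrs."""
    with h5py.File(path, "a") as f:
        grp = f.require_group(f"{subject_id}/{seq.atlas_id}")
        if "dfc" in grp:
            del grp["dfc"]
        ds = grp.create_dataset("dfc", data=seq.data)
        ds.attrs["W"] = seq.params.window_volumes
        ds.attrs["S"] = seq.params.step_volumes
        ds.attrs["TR"] = tr_seconds
        ds.attrs["Ts"] = ts


def load_dfc_cache(path, subject_id: str, atlas_id: str) -> DfcSequence:
    with h5py.File(path, "r") as f:
        ds = f[f"{subject_id}/{atlas_id}/dfc"]
        params = DfcParams(int(ds.attrs["W"]), int(ds.attrs["S"]))
        return DfcSequence(data=ds[()], atlas_id=atlas_id, params=params)
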
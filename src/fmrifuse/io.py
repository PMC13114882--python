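"""Input handling: BOLD volumes, atlas label volumes, phenotype tables,
regional time-series extraction, and voxel-clip sampling.

Indexing is 0-based half-open throughout.  A clip with start index ``t0``,
length ``T`` and within-clip stride ``delta`` consists of source volumes
``t0, t0 + delta, ..., t0 + (T-1) * delta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldVolume4D",
    "AtlasLabelVolume",
    "RegionalTimeSeries",
    "Clip",
    "load_bold",
    "load_atlas",
    "load_phenotypes",
    "extract_regional_timeseries",
    "sample_clip",
    "enumerate_clip_starts",
    "random_clip_start",
    "PHENOTYPE_COLUMNS",
]


@dataclass
class BoldVolume4D:
    """Preprocessed 4D BOLD data, axes ordered [Z, Y, X, Ts]."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4 dimensions, got {self.data.ndim}")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one volume")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class AtlasLabelVolume:
    """Integer parcellation volume; 0 is background, ROIs are 1..n_rois."""

    labels: np.ndarray
    atlas_id: str
    n_rois: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if self.labels.min() < 0 or self.labels.max() > self.n_rois:
            raise ValueError("labels outside 0..n_rois")

    def empty_rois(self) -> list[int]:
        present = np.bincount(self.labels.ravel(), minlength=self.n_rois + 1)
        return [r for r in range(1, self.n_rois + 1) if present[r] == 0]


@dataclass
class RegionalTimeSeries:
    """ROI-mean BOLD signals, shape [Ts, Na]."""

    values: np.ndarray
    atlas_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("regional time series must be [Ts, Na]")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class Clip:
    """Fixed-size voxel excerpt [side, side, side, T] taken from a BOLD scan."""

    data: np.ndarray
    t0: int
    delta: int
    T: int = field(init=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("clip must be 4D")
        self.T = self.data.shape[3]


def load_bold(path, tr_seconds: float | None = None, subject_id: str = "",
              nan_to_zero: bool = False) -> BoldVolume4D:
    """Load a 4D NIfTI BOLD image.

    The repetition time defaults to the header's 4th zoom and can be
    overridden by ``tr_seconds``.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4 dimensions, got {img.ndim} in {path}")
    data = np.asarray(img.dataobj)
    if np.isnan(data).any():
        if not nan_to_zero:
            raise ValueError(f"NaN voxels in {path}; pass nan_to_zero=True to zero them")
        data = np.nan_to_num(data)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return BoldVolume4D(data=data, tr_seconds=float(tr_seconds), subject_id=subject_id)


def load_atlas(path, atlas_id: str, n_rois: int | None = None) -> AtlasLabelVolume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D label image, got {img.ndim}D in {path}")
    labels = np.asarray(img.dataobj).round().astype(np.int64)
    if n_rois is None:
        n_rois = int(labels.max())
    return AtlasLabelVolume(labels=labels, atlas_id=atlas_id, n_rois=n_rois)


#: canonical phenotype column names (ABIDE-style)
PHENOTYPE_COLUMNS = {
    "subject_id": "SUB_ID",
    "diagnosis": "DX_GROUP",
    "site_id": "SITE_ID",
    "sex": "SEX",
    "age": "AGE_AT_SCAN",
    "fiq": "FIQ",
    "eye_status": "EYE_STATUS_AT_SCAN",
}


def load_phenotypes(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a phenotype CSV into a normalized table.

    Returns a DataFrame indexed by ``subject_id`` with columns
    ``diagnosis`` (ASD/TC), ``site_id``, ``sex`` (M/F), ``age``, ``fiq``,
    ``eye_status`` (Open/Closed/NA).  ``DX_GROUP`` uses the ABIDE convention
    1 = ASD, 2 = TC; ``SEX`` 1 = M, 2 = F.
    """
    cols = dict(PHENOTYPE_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    df = pd.DataFrame(
        {
            "subject_id": raw[cols["subject_id"]].astype(str),
            "diagnosis": raw[cols["diagnosis"]].map({1: "ASD", 2: "TC", "ASD": "ASD", "TC": "TC"}),
            "site_id": raw[cols["site_id"]].astype(str),
            "sex": raw[cols["sex"]].map({1: "M", 2: "F", "M": "M", "F": "F"}),
            "age": pd.to_numeric(raw[cols["age"]], errors="coerce"),
            "fiq": pd.to_numeric(raw[cols["fiq"]], errors="coerce"),
            "eye_status": raw[cols["eye_status"]].fillna("NA").astype(str),
        }
    )
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in phenotype table")
    if df["diagnosis"].isna().any() or df["site_id"].isna().any():
        raise ValueError("diagnosis and site_id must be non-missing")
    return df.set_index("subject_id")


def extract_regional_timeseries(bold: BoldVolume4D,
                                atlas: AtlasLabelVolume) -> RegionalTimeSeries:
    """ROI-mean time series: column r-1 is the mean over voxels labeled r.

    Empty ROIs yield a zero column and a warning (reported, not fatal, so
    cropped or synthetic atlases still run).
    """
    if bold.spatial_shape != atlas.labels.shape:
        raise ValueError(
            f"spatial shape mismatch: bold {bold.spatial_shape} vs atlas {atlas.labels.shape}"
        )
    labels = atlas.labels.ravel()
    na = atlas.n_rois
    flat = bold.data.reshape(-1, bold.n_volumes)
    counts = np.bincount(labels, minlength=na + 1).astype(np.float64)
    sums = np.zeros((na + 1, bold.n_volumes))
    np.add.at(sums, labels, flat)
    empty = counts[1:] == 0
    if empty.any():
        warnings.warn(
            f"atlas {atlas.atlas_id}: empty ROIs {np.flatnonzero(empty) + 1}; "
            "their columns are zero"
        )
    counts[counts == 0] = 1.0
    values = (sums / counts[:, None])[1:].T  # [Ts, Na]
    values[:, empty] = 0.0
    return RegionalTimeSeries(values=values, atlas_id=atlas.atlas_id)


def _pad_or_crop_axis(arr: np.ndarray, axis: int, target: int) -> np.ndarray:
    size = arr.shape[axis]
    if size == target:
        return arr
    if size < target:
        deficit = target - size
        lo = deficit // 2
        hi = deficit - lo  # extra voxel goes on the high-index side
        width = [(0, 0)] * arr.ndim
        width[axis] = (lo, hi)
        return np.pad(arr, width)
    excess = size - target
    lo = excess // 2
    sl = [slice(None)] * arr.ndim
    sl[axis] = slice(lo, lo + target)
    return arr[tuple(sl)]


def sample_clip(bold: BoldVolume4D, t0: int, T: int, delta: int = 1,
                side: int = 96) -> Clip:
    """Extract volumes ``t0, t0+delta, ...`` and standardize each to side^3
    by symmetric zero-padding / center-cropping (odd deficit: extra voxel on
    the high side)."""
    ts = bold.n_volumes
    last = t0 + (T - 1) * delta
    if t0 < 0 or last >= ts:
        max_t0 = ts - 1 - (T - 1) * delta
        raise ValueError(
            f"clip [{t0}..{last}] overruns scan of {ts} volumes; "
            f"maximal admissible t0 is {max_t0}"
        )
    frames = bold.data[..., t0: last + 1: delta]
    for axis in range(3):
        frames = _pad_or_crop_axis(frames, axis, side)
    return Clip(data=frames, t0=t0, delta=delta)


def enumerate_clip_starts(ts: int, T: int, delta: int = 1,
                          eval_stride: int = 10) -> list[int]:
    """Deterministic evaluation grid of clip starts: multiples of
    ``eval_stride`` that admit a full clip."""
    max_t0 = ts - 1 - (T - 1) * delta
    if max_t0 < 0:
        raise ValueError(f"scan of {ts} volumes too short for T={T}, delta={delta}")
    return list(range(0, max_t0 + 1, eval_stride))


def random_clip_start(ts: int, T: int, delta: int,
                      rng: np.random.Generator) -> int:
    """Uniform random valid start index (training-time clip sampling)."""
    max_t0 = ts - 1 - (T - 1) * delta
    if max_t0 < 0:
        raise ValueError(f"scan of {ts} volumes too short for T={T}, delta={delta}")
    return int(rng.integers(0, max_t0 + 1))
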
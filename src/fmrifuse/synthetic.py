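"""Synthetic two-class rs-fMRI cohorts with time-varying coupling.

The generator emulates the structure the pipeline consumes — ROI-organized
BOLD with class-dependent dynamic coupling, multi-site offsets and
observation noise — without claiming physiological realism:

* A "generator" parcellation (the first atlas spec) defines latent ROI
  signals: AR(1) processes driven by unit-variance innovations.
* During "on" half-periods of ``switch_period`` volumes the innovations of
  each coupling pair are correlated (``base_rho`` for class 0,
  ``base_rho + delta_rho`` for class 1); during "off" half-periods all
  innovations are independent.  Block switching makes the dynamic signal
  unambiguous for sliding windows and gives closed-form targets for tests.
* Every voxel carries its generator-ROI latent signal plus a per-site
  constant offset and white observation noise.  Additional atlases are
  independent Voronoi parcellations of the same volume, so their regional
  series are mixtures of latent signals (parcellation-mismatch realism).

All randomness flows from one root seed through named
``numpy.random.SeedSequence`` streams (atlas / site / phenotype /
per-subject), so any piece is independently reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data import SubjectRecord
from .io import AtlasLabelVolume, BoldVolume4D, extract_regional_timeseries

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "make_synthetic_atlas",
    "simulate_subject",
    "make_dataset",
    "coupled_rois",
    "on_window_mask",
]

_BURN_IN = 50  # AR(1) warm-up volumes discarded before t=0


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 60
    class_balance: float = 0.5
    n_sites: int = 3
    site_offset_sd: float = 0.5
    vol_shape: tuple[int, int, int] = (24, 24, 24)
    ts: int = 240
    tr_seconds: float = 2.0
    atlas_specs: tuple[tuple[str, int], ...] = (
        ("atlasA", 12), ("atlasB", 10), ("atlasC", 16))
    coupling_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3))
    base_rho: float = 0.1
    delta_rho: float = 0.6
    switch_period: int = 30
    ar_coef: float = 0.3
    obs_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.delta_rho < 1:
            raise ValueError("delta_rho must be in [0, 1)")
        if abs(self.base_rho + self.delta_rho) > 0.95:
            raise ValueError("|base_rho + delta_rho| must not exceed 0.95")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must be in [0, 1)")
        na0 = self.atlas_specs[0][1]
        flat = [r for pair in self.coupling_pairs for r in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("coupling pairs must be disjoint")
        if flat and max(flat) >= na0:
            raise ValueError("coupling ROI index outside the generator atlas")


@dataclass
class SyntheticDataset:
    records: list[SubjectRecord]
    atlases: dict[str, AtlasLabelVolume]
    phenotypes: pd.DataFrame
    config: SimConfig


def coupled_rois(cfg: SimConfig) -> list[int]:
    """Sorted 0-based generator-atlas ROIs that carry the class signal."""
    return sorted({r for pair in cfg.coupling_pairs for r in pair})


def on_window_mask(ts: int, switch_period: int) -> np.ndarray:
    """Boolean per-volume mask of coupling "on" half-periods (periodic,
    starting on at t=0)."""
    return (np.arange(ts) // switch_period) % 2 == 0


def make_synthetic_atlas(vol_shape: tuple[int, int, int], n_rois: int,
                         rng: np.random.Generator | int,
                         atlas_id: str = "atlas") -> AtlasLabelVolume:
    """Voronoi parcellation: seed voxels drawn without replacement, every
    voxel labeled by its nearest seed (1..Na); no ROI is empty because each
    seed voxel is its own nearest seed."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n_vox = int(np.prod(vol_shape))
    if n_rois > n_vox:
        raise ValueError(f"{n_rois} ROIs exceed {n_vox} voxels")
    coords = np.stack(np.unravel_index(np.arange(n_vox), vol_shape), axis=1)
    seeds = coords[rng.choice(n_vox, size=n_rois, replace=False)]
    _, nearest = cKDTree(seeds).query(coords)
    labels = (nearest + 1).reshape(vol_shape).astype(np.int64)
    return AtlasLabelVolume(labels=labels, atlas_id=atlas_id, n_rois=n_rois)


def _latent_signals(cfg: SimConfig, label: int, rng: np.random.Generator) -> np.ndarray:
    """AR(1) generator-ROI signals [Ts, Na0] with switching coupling."""
    na0 = cfg.atlas_specs[0][1]
    total = cfg.ts + _BURN_IN
    e = rng.standard_normal((total, na0))
    # periodic on/off mask, consistent across the burn-in extension
    t_axis = np.arange(-_BURN_IN, cfg.ts)
    on = (t_axis % (2 * cfg.switch_period)) < cfg.switch_period
    rho_on = cfg.base_rho + (cfg.delta_rho if label == 1 else 0.0)
    rho_t = np.where(on, rho_on, 0.0)
    for i, j in cfg.coupling_pairs:
        e[:, j] = rho_t * e[:, i] + np.sqrt(1.0 - rho_t**2) * e[:, j]
    x = np.zeros((total, na0))
    x[0] = e[0] / np.sqrt(1.0 - cfg.ar_coef**2)  # stationary start
    for t in range(1, total):
        x[t] = cfg.ar_coef * x[t - 1] + e[t]
    return x[_BURN_IN:]


def simulate_subject(cfg: SimConfig, label: int, site_offset: float,
                     rng: np.random.Generator,
                     gen_atlas: AtlasLabelVolume,
                     subject_id: str = "") -> BoldVolume4D:
    """Voxel BOLD = generator-ROI latent + site constant + white noise."""
    latents = _latent_signals(cfg, label, rng)  # [Ts, Na0]
    roi_of_voxel = gen_atlas.labels - 1         # [Z, Y, X]
    data = latents.T[roi_of_voxel]              # [Z, Y, X, Ts]
    data = data + site_offset
    if cfg.obs_noise_sd > 0:
        # float32 stream: observation noise dominates generation cost
        data = data + cfg.obs_noise_sd * rng.standard_normal(data.shape,
                                                             dtype=np.float32)
    return BoldVolume4D(data=data.astype(np.float32), tr_seconds=cfg.tr_seconds,
                        subject_id=subject_id)


def _phenotype_row(rng: np.random.Generator) -> dict:
    sex = "M" if rng.random() < 0.8 else "F"
    age = float(np.clip(rng.normal(17.0, 8.0), 6.0, 60.0))
    fiq = float(rng.normal(108.0, 15.0)) if rng.random() > 0.05 else np.nan
    eye = "Open" if rng.random() < 0.7 else "Closed"
    return {"sex": sex, "age": round(age, 1),
            "fiq": round(fiq, 1) if np.isfinite(fiq) else np.nan,
            "eye_status": eye}


def make_dataset(cfg: SimConfig, out_dir=None, overwrite: bool = False
                 ) -> SyntheticDataset:
    """Build a full synthetic cohort (optionally written to disk as NIfTI +
    manifest CSV in the layout the loaders expect).

    Diagnoses and sites are assigned so that every site is class-balanced:
    sites are rotated within each diagnostic group, making site identity
    uninformative by construction unless the caller skews ``class_balance``
    or site assignment downstream.
    """
    root = np.random.SeedSequence(cfg.seed)
    atlas_ss, site_ss, pheno_ss, subjects_ss = root.spawn(4)
    atlas_streams = atlas_ss.spawn(len(cfg.atlas_specs))
    atlases = {
        aid: make_synthetic_atlas(cfg.vol_shape, na,
                                  np.random.default_rng(stream), atlas_id=aid)
        for (aid, na), stream in zip(cfg.atlas_specs, atlas_streams)
    }
    gen_atlas = atlases[cfg.atlas_specs[0][0]]
    site_rng = np.random.default_rng(site_ss)
    site_ids = [f"SITE{i}" for i in range(cfg.n_sites)]
    site_offsets = dict(zip(site_ids, site_rng.normal(0.0, cfg.site_offset_sd,
                                                      cfg.n_sites)))
    pheno_rng = np.random.default_rng(pheno_ss)
    n_asd = int(round(cfg.n_subjects * cfg.class_balance))
    labels = [1] * n_asd + [0] * (cfg.n_subjects - n_asd)
    subject_streams = subjects_ss.spawn(cfg.n_subjects)
    records, rows = [], []
    class_counter = {0: 0, 1: 0}
    for i, (label, stream) in enumerate(zip(labels, subject_streams)):
        sid = f"{50000 + i}"
        site = site_ids[class_counter[label] % cfg.n_sites]
        class_counter[label] += 1
        bold = simulate_subject(cfg, label, site_offsets[site],
                                np.random.default_rng(stream), gen_atlas,
                                subject_id=sid)
        series = {aid: extract_regional_timeseries(bold, atlas)
                  for aid, atlas in atlases.items()}
        diagnosis = "ASD" if label == 1 else "TC"
        records.append(SubjectRecord(subject_id=sid, bold=bold, series=series,
                                     diagnosis=diagnosis, site_id=site))
        rows.append({"SUB_ID": sid, "DX_GROUP": 1 if label == 1 else 2,
                     "SITE_ID": site, **{
                         {"sex": "SEX", "age": "AGE_AT_SCAN", "fiq": "FIQ",
                          "eye_status": "EYE_STATUS_AT_SCAN"}[k]: v
                         for k, v in _phenotype_row(pheno_rng).items()
                     }})
    manifest = pd.DataFrame(rows)
    manifest["SEX"] = manifest["SEX"].map({"M": 1, "F": 2})
    dataset = SyntheticDataset(records=records, atlases=atlases,
                               phenotypes=manifest, config=cfg)
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir), overwrite)
    return dataset


def _write_dataset(dataset: SyntheticDataset, out_dir: Path,
                   overwrite: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    for aid, atlas in dataset.atlases.items():
        nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4)),
                 out_dir / f"atlas_{aid}.nii.gz")
    for rec in dataset.records:
        img = nib.Nifti1Image(rec.bold.data.astype(np.float32), np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, rec.bold.tr_seconds))
        nib.save(img, out_dir / f"sub-{rec.subject_id}_bold.nii.gz")
    dataset.phenotypes.to_csv(out_dir / "manifest.csv", index=False)
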
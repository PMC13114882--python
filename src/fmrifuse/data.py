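"""Subject-level data records tying together BOLD, regional series and dFC."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dfc import DfcParams, DfcSequence, build_dfc_sequence, load_dfc_cache, save_dfc_cache
from .io import (
    AtlasLabelVolume,
    BoldVolume4D,
    RegionalTimeSeries,
    extract_regional_timeseries,
    load_atlas,
    load_bold,
    load_phenotypes,
)

__all__ = ["SubjectRecord", "prepare_dfc", "load_cohort", "phenotype_frame"]


@dataclass
class SubjectRecord:
    """Everything the classifier needs for one subject."""

    subject_id: str
    bold: BoldVolume4D
    series: dict[str, RegionalTimeSeries]
    diagnosis: str  # "ASD" | "TC"
    site_id: str
    dfc: dict[str, DfcSequence] = field(default_factory=dict)

    @property
    def label(self) -> int:
        """ASD is the positive class (ABIDE DX_GROUP=1)."""
        return 1 if self.diagnosis == "ASD" else 0


def prepare_dfc(records: list[SubjectRecord], params: DfcParams,
                cache_path=None) -> None:
    """Compute (or load from an HDF5 cache) dFC sequences for every record.

    The cache is keyed by (subject, atlas); entries with mismatching window
    parameters are recomputed.
    """
    for rec in records:
        for atlas_id, series in rec.series.items():
            if atlas_id in rec.dfc and rec.dfc[atlas_id].params == params:
                continue
            seq = None
            if cache_path is not None and Path(cache_path).exists():
                try:
                    cached = load_dfc_cache(cache_path, rec.subject_id, atlas_id)
                    if cached.params == params:
                        seq = cached
                except KeyError:
                    seq = None
            if seq is None:
                seq = build_dfc_sequence(series, params)
                if cache_path is not None:
                    save_dfc_cache(cache_path, rec.subject_id, seq,
                                   rec.bold.tr_seconds, rec.bold.n_volumes)
            rec.dfc[atlas_id] = seq


def load_cohort(root, atlas_specs: list[tuple[str, int]] | None = None
                ) -> tuple[list[SubjectRecord], dict[str, AtlasLabelVolume], pd.DataFrame]:
    """Load a directory laid out by the synthetic generator:
    ``manifest.csv``, ``atlas_<id>.nii.gz``, ``sub-<id>_bold.nii.gz``."""
    root = Path(root)
    pheno = load_phenotypes(root / "manifest.csv")
    if atlas_specs is None:
        atlas_specs = [
            (p.name.removeprefix("atlas_").removesuffix(".nii.gz"), None)
            for p in sorted(root.glob("atlas_*.nii.gz"))
        ]
    atlases = {
        aid: load_atlas(root / f"atlas_{aid}.nii.gz", aid, n_rois)
        for aid, n_rois in atlas_specs
    }
    records = []
    for sid, row in pheno.iterrows():
        bold = load_bold(root / f"sub-{sid}_bold.nii.gz", subject_id=sid)
        series = {aid: extract_regional_timeseries(bold, atlas)
                  for aid, atlas in atlases.items()}
        records.append(SubjectRecord(
            subject_id=sid, bold=bold, series=series,
            diagnosis=row["diagnosis"], site_id=row["site_id"],
        ))
    return records, atlases, pheno


def phenotype_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Minimal phenotype table (diagnosis, site) derived from records."""
    return pd.DataFrame(
        {
            "diagnosis": [r.diagnosis for r in records],
            "site_id": [r.site_id for r in records],
        },
        index=pd.Index([r.subject_id for r in records], name="subject_id"),
    )
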
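"""Attention-based ROI attribution.

For correctly classified subjects the importance of ROI ``r`` combines the
L2 norm of its final-layer token feature with the total attention it
receives (column sum of the row-stochastic ROI attention matrix, self-term
included):

    Score(r) = (1/B) * sum_b  W[b, r] * F[b, r]

An attention-derived connectivity matrix is obtained by averaging each
subject's ROI attention and symmetrizing, and the top-k ROIs by score (ties
broken by ascending ROI index) select the reported k x k submatrix.

ROI-indexed features and attention require the dFC encoder to run in
``roi_token_mode`` (one token per ROI per frame); token features are
averaged over frames, attention over heads and frame pairs, and rows are
renormalized to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SubjectRecord
from .fusion import GatedFusionClassifier
from .io import enumerate_clip_starts

__all__ = [
    "AttributionResult",
    "roi_feature_norms",
    "attention_inflow",
    "roi_scores",
    "attention_fc",
    "top_k_submatrix",
    "attribute",
    "collect_attention",
    "export_viewer_files",
]


@dataclass
class AttributionResult:
    scores: np.ndarray       # [N]
    fc_sym: np.ndarray       # [N, N], symmetric
    top_ids: np.ndarray      # [k], descending score
    fc_top: np.ndarray       # [k, k]
    atlas_id: str = ""
    subject_ids: tuple = ()


def roi_feature_norms(features: np.ndarray) -> np.ndarray:
    """F[b, r] = ||z[b, r, :]||_2 for features [B, N, Dd]."""
    return np.linalg.norm(np.asarray(features, dtype=np.float64), axis=-1)


def attention_inflow(attn: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """W[b, r] = sum_j A[b, j, r] (column sums, self-term included)."""
    a = np.asarray(attn, dtype=np.float64)
    row_sums = a.sum(axis=-1)
    if np.abs(row_sums - 1.0).max() > tol:
        warnings.warn("attention rows do not sum to 1; proceeding anyway")
    return a.sum(axis=-2)


def roi_scores(feature_norms: np.ndarray, inflow: np.ndarray) -> np.ndarray:
    """Mean over subjects of inflow * feature norm."""
    f = np.asarray(feature_norms, dtype=np.float64)
    w = np.asarray(inflow, dtype=np.float64)
    if f.shape != w.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {w.shape}")
    if f.ndim != 2 or f.shape[0] == 0:
        raise ValueError("no correctly classified subjects")
    return (w * f).mean(axis=0)


def attention_fc(attn: np.ndarray) -> np.ndarray:
    """Subject-averaged attention, symmetrized: (FC + FC^T) / 2."""
    a = np.asarray(attn, dtype=np.float64)
    if a.ndim != 3 or a.shape[0] == 0:
        raise ValueError("need attention for at least one subject")
    fc = a.mean(axis=0)
    return (fc + fc.T) / 2.0


def top_k_submatrix(scores: np.ndarray, fc_sym: np.ndarray,
                    k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the k largest scores (ties -> ascending ROI index) and the
    corresponding submatrix of ``fc_sym`` in score order."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} ROIs")
    order = np.lexsort((np.arange(n), -scores))
    ids = order[:k]
    return ids, fc_sym[np.ix_(ids, ids)]


def attribute(features: np.ndarray, attn: np.ndarray, k: int = 10,
              atlas_id: str = "", subject_ids=()) -> AttributionResult:
    """Full scoring pipeline from ROI features and ROI attention."""
    f = roi_feature_norms(features)
    w = attention_inflow(attn)
    scores = roi_scores(f, w)
    fc_sym = attention_fc(attn)
    top_ids, fc_top = top_k_submatrix(scores, fc_sym, k)
    return AttributionResult(scores=scores, fc_sym=fc_sym, top_ids=top_ids,
                             fc_top=fc_top, atlas_id=atlas_id,
                             subject_ids=tuple(subject_ids))


def collect_attention(clf: GatedFusionClassifier, records: list[SubjectRecord],
                      atlas_id: str, who: str = "asd"
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """ROI token features and ROI attention for correctly classified subjects.

    ``who='asd'`` keeps only correctly classified ASD subjects; ``'all'``
    keeps every correctly classified subject.  For each kept subject the
    dFC encoder (which must be in ``roi_token_mode``) is run over the
    evaluation clip grid; final-layer ROI tokens are averaged over clips
    and frames, final-layer attention over clips, heads and frame pairs,
    then renormalized row-stochastic.

    Returns ``(features [B, N, Dd], attention [B, N, N], subject_ids)``.
    """
    if who not in ("asd", "all"):
        raise ValueError("who must be 'asd' or 'all'")
    if clf.dfc_encoder_ is None:
        raise RuntimeError("model has no dFC branch")
    if not clf.dfc_encoder_.cfg.roi_token_mode:
        raise RuntimeError("ROI attribution needs roi_token_mode=True")
    encoder = clf.dfc_encoder_.encoders[atlas_id]
    na, L = encoder.n_rois, encoder.n_frames
    feats, attns, kept = [], [], []
    for rec in records:
        probs, _ = clf.predict_subject(rec)
        if int(probs.argmax()) != rec.label:
            continue
        if who == "asd" and rec.diagnosis != "ASD":
            continue
        starts = enumerate_clip_starts(rec.bold.n_volumes, clf.clip_length,
                                       clf.clip_stride, clf.eval_stride)
        from .dfc import dfc_bundle  # local import avoids a cycle at module load
        aligned = np.stack([
            dfc_bundle(rec.dfc, t0, clf.clip_length, clf.clip_stride,
                       L_override=clf.L_override, atlases=[atlas_id])[atlas_id].data
            for t0 in starts
        ])
        n = encoder.n_tokens  # register tokens, if any, are not attributed
        tokens = encoder.encode_tokens(aligned, record=True).data[:, :n]
        attn = encoder.final_attention()[:, :, :n, :n]
        feats.append(tokens.reshape(len(starts), L, na, -1).mean(axis=(0, 1)))
        a = attn.mean(axis=1).reshape(len(starts), L, na, L, na)
        a = a.mean(axis=(0, 1, 3))                                 # [Na, Na]
        a = a / a.sum(axis=1, keepdims=True)
        attns.append(a)
        kept.append(rec.subject_id)
    if not kept:
        raise RuntimeError("no correctly classified qualifying subjects")
    return np.stack(feats), np.stack(attns), kept


def export_viewer_files(result: AttributionResult, roi_meta: pd.DataFrame,
                        node_path, edge_path, table_path=None) -> None:
    """Write BrainNet-Viewer-style plain-text files for the top-k ROIs.

    ``roi_meta`` is indexed by 0-based ROI id with columns ``x, y, z``
    (centroid coordinates), ``name`` and optionally ``abbr``.  The .node
    format is ``x y z color size label`` per row; the .edge file is the
    k x k connectivity submatrix.
    """
    missing = [int(i) for i in result.top_ids if i not in roi_meta.index]
    if missing:
        raise ValueError(f"no coordinates for ROI(s): {missing}")
    top_scores = result.scores[result.top_ids]
    smax = top_scores.max() if top_scores.max() > 0 else 1.0
    lines = []
    for rank, roi in enumerate(result.top_ids):
        row = roi_meta.loc[int(roi)]
        label = str(row.get("abbr", row.get("name", f"ROI{roi + 1}"))).replace(" ", "_")
        lines.append(f"{row['x']:.3f}\t{row['y']:.3f}\t{row['z']:.3f}\t"
                     f"1\t{top_scores[rank] / smax:.4f}\t{label}")
    Path(node_path).write_text("\n".join(lines) + "\n")
    np.savetxt(edge_path, result.fc_top, fmt="%.6f", delimiter="\t")
    if table_path is not None:
        pd.DataFrame({
            "Region": [str(roi_meta.loc[int(r)].get("name", f"ROI{r + 1}"))
                       for r in result.top_ids],
            "Abbr": [str(roi_meta.loc[int(r)].get("abbr", f"ROI{r + 1}"))
                     for r in result.top_ids],
            "Score": top_scores,
        }).to_csv(table_path, index=False)
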
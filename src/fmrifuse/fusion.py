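"""Gated late fusion, training, cross-validation and evaluation.

The two branch embeddings are mapped to class logits by lightweight linear
heads; the fused logit is ``z = alpha * z_vox + (1 - alpha) * z_dfc`` with
``alpha = sigmoid(beta)`` and ``beta`` a trainable scalar.  Training
optimizes softmax cross-entropy with AdamW.  Evaluation is subject-wise:
fused logits are averaged over a uniform grid of clip starts, then
softmaxed.

Ablation modes mirror the controlled variants:

- ``dfc_only``   — dFC pathway alone (``z = z_dfc``)
- ``voxel_only`` — voxel pathway alone (``z = z_vox``)
- ``fixed_fusion`` — gate frozen at ``alpha = 1/2``
- ``full``       — learnable gate (default)

Cross-validation is subject-wise and jointly stratified on diagnosis and
acquisition site: subjects are grouped into (diagnosis, site) strata,
shuffled with the fold seed, and dealt round-robin (with a random starting
fold per stratum) so per-stratum fold counts differ by at most one.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score, precision_score, roc_auc_score

from . import nn
from .backbone import BackboneConfig, VoxelTransformer4D
from .data import SubjectRecord, phenotype_frame, prepare_dfc
from .dfc import DfcParams, aligned_length, dfc_bundle
from .dfc_encoder import DfcEncoderConfig, MultiAtlasDfcEncoder
from .io import enumerate_clip_starts, random_clip_start, sample_clip
from .nn import Tensor

__all__ = [
    "MODES",
    "FoldAssignment",
    "gated_fuse",
    "classification_loss",
    "stratified_subject_folds",
    "fold_balance_report",
    "evaluate_predictions",
    "site_only_baseline",
    "GatedFusionClassifier",
    "cross_validate",
]

MODES = ("full", "dfc_only", "voxel_only", "fixed_fusion")


# ---------------------------------------------------------------------------
# fusion primitives
# ---------------------------------------------------------------------------

def gated_fuse(z_vox: np.ndarray, z_dfc: np.ndarray, beta: float) -> np.ndarray:
    """``sigmoid(beta) * z_vox + (1 - sigmoid(beta)) * z_dfc``."""
    z_vox = np.asarray(z_vox, dtype=np.float64)
    z_dfc = np.asarray(z_dfc, dtype=np.float64)
    if z_vox.shape != z_dfc.shape:
        raise ValueError(f"logit shapes differ: {z_vox.shape} vs {z_dfc.shape}")
    alpha = 1.0 / (1.0 + np.exp(-float(beta)))
    return alpha * z_vox + (1.0 - alpha) * z_dfc


def classification_loss(z: np.ndarray, y_onehot: np.ndarray) -> float:
    """Softmax cross-entropy ``-sum_c y_c log softmax(z)_c`` (mean over a
    leading batch axis if present)."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y_onehot, dtype=np.float64)
    zc = z - z.max(axis=-1, keepdims=True)
    logp = zc - np.log(np.exp(zc).sum(axis=-1, keepdims=True))
    return float(np.mean(-(y * logp).sum(axis=-1)))


def softmax_probs(z: np.ndarray) -> np.ndarray:
    zc = np.asarray(z, dtype=np.float64)
    zc = zc - zc.max(axis=-1, keepdims=True)
    e = np.exp(zc)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# subject-wise stratified folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold_of_subject: dict[str, int]
    k: int
    seed: int

    def subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_subject.items() if f == fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of_subject.items() if f != fold]


def stratified_subject_folds(phenotypes: pd.DataFrame, k: int,
                             seed: int = 0) -> FoldAssignment:
    """Deal each (diagnosis, site) stratum round-robin into ``k`` folds.

    Subjects within a stratum are shuffled with the seed and the starting
    fold of each stratum is drawn at random, so per-fold per-stratum counts
    differ by at most one while fold sizes stay balanced.
    """
    if phenotypes["diagnosis"].isna().any() or phenotypes["site_id"].isna().any():
        raise ValueError("every subject needs diagnosis and site_id")
    n = len(phenotypes)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} invalid for {n} subjects")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    strata = phenotypes.groupby(["diagnosis", "site_id"], sort=True).groups
    for key in sorted(strata):
        ids = sorted(str(s) for s in strata[key])
        order = rng.permutation(len(ids))
        start = int(rng.integers(k))
        for j, idx in enumerate(order):
            assignment[ids[idx]] = (start + j) % k
    return FoldAssignment(fold_of_subject=assignment, k=k, seed=seed)


def fold_balance_report(phenotypes: pd.DataFrame,
                        folds: FoldAssignment) -> pd.DataFrame:
    """Per-fold summary of the confounder distribution (N, class split,
    sites, sex ratio, age, FIQ on the FIQ>0 subset, eye status)."""
    rows = []
    fold_series = pd.Series(folds.fold_of_subject, name="fold")
    df = phenotypes.join(fold_series, how="inner")
    for fold in range(folds.k):
        sub = df[df["fold"] == fold]
        fiq = sub["fiq"] if "fiq" in sub else pd.Series(dtype=float)
        fiq_valid = fiq[(fiq > 0) & fiq.notna()]
        eye = sub.get("eye_status", pd.Series(dtype=object))
        rows.append({
            "fold": fold + 1,
            "N": len(sub),
            "ASD": int((sub["diagnosis"] == "ASD").sum()),
            "TC": int((sub["diagnosis"] == "TC").sum()),
            "n_sites": sub["site_id"].nunique(),
            "M": int((sub.get("sex") == "M").sum()),
            "F": int((sub.get("sex") == "F").sum()),
            "age_mean": float(sub["age"].mean()) if "age" in sub else np.nan,
            "age_sd": float(sub["age"].std()) if "age" in sub else np.nan,
            "fiq_n": int(fiq_valid.count()),
            "fiq_mean": float(fiq_valid.mean()) if len(fiq_valid) else np.nan,
            "fiq_sd": float(fiq_valid.std()) if len(fiq_valid) else np.nan,
            "eye_open": int((eye == "Open").sum()),
            "eye_closed": int((eye == "Closed").sum()),
            "eye_na": int((~eye.isin(["Open", "Closed"])).sum()) if len(eye) else 0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate_predictions(y_true: np.ndarray, prob_pos: np.ndarray,
                         threshold: float = 0.5) -> dict[str, float]:
    """Subject-level Acc / Prec / F1 / AUC (positive class = ASD = 1).

    AUC is the Mann-Whitney rank statistic (midranks on ties); it is NaN
    with a warning when the fold contains a single class.
    """
    y_true = np.asarray(y_true, dtype=int)
    prob_pos = np.asarray(prob_pos, dtype=float)
    y_pred = (prob_pos >= threshold).astype(int)
    out = {
        "Acc": accuracy_score(y_true, y_pred),
        "Prec": precision_score(y_true, y_pred, zero_division=0),
        "F1": f1_score(y_true, y_pred, zero_division=0),
    }
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class fold: AUC undefined, reported as NaN")
        out["AUC"] = float("nan")
    else:
        out["AUC"] = roc_auc_score(y_true, prob_pos)
    return out


def site_only_baseline(phenotypes: pd.DataFrame, folds: FoldAssignment,
                       seed: int = 0) -> pd.DataFrame:
    """Diagnosis prediction from one-hot site identity alone (logistic
    regression per training fold) — the multi-site confounding sanity check."""
    sites = sorted(phenotypes["site_id"].unique())
    if len(sites) < 2:
        warnings.warn("single acquisition site: site-only baseline is degenerate")
    site_index = {s: i for i, s in enumerate(sites)}
    x = np.zeros((len(phenotypes), len(sites)))
    x[np.arange(len(phenotypes)),
      [site_index[s] for s in phenotypes["site_id"]]] = 1.0
    y = (phenotypes["diagnosis"] == "ASD").astype(int).to_numpy()
    ids = list(phenotypes.index.astype(str))
    pos = {s: i for i, s in enumerate(ids)}
    rows = []
    for fold in range(folds.k):
        test = [pos[s] for s in folds.subjects(fold)]
        train = [pos[s] for s in folds.train_subjects(fold)]
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit(x[train], y[train])
        prob = clf.predict_proba(x[test])[:, 1]
        m = evaluate_predictions(y[test], prob)
        rows.append({"fold": fold, **m})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class GatedFusionClassifier(BaseEstimator, ClassifierMixin):
    """Dual-branch rs-fMRI classifier with learnable gated logit fusion.

    Parameters mirror the two branch configurations plus the sampling and
    optimization knobs.  ``fit`` takes a list of :class:`SubjectRecord`;
    labels default to the records' diagnosis (ASD = positive class = 1).

    Fitted attributes (trailing underscore): ``backbone_``,
    ``dfc_encoder_``, ``head_vox_``, ``head_dfc_``, ``beta_``, ``alpha_``,
    ``history_``, ``n_epochs_``, ``classes_``.
    """

    def __init__(self, backbone_cfg: BackboneConfig | None = None,
                 dfc_cfg: DfcEncoderConfig | None = None, mode: str = "full",
                 atlases: list[str] | None = None, clip_side: int = 24,
                 clip_length: int = 8, clip_stride: int = 1,
                 window_volumes: int = 30, step_volumes: int = 2,
                 L_override: int | None = None, eval_stride: int = 10,
                 val_stride: int = 60, lr: float = 1e-4,
                 weight_decay: float = 0.01, batch_size: int = 16,
                 max_epochs: int = 50, patience: int = 10,
                 val_fraction: float = 0.2, grad_clip: float | None = 1.0,
                 warmup_epochs: int = 5, seed: int = 0):
        self.backbone_cfg = backbone_cfg
        self.dfc_cfg = dfc_cfg
        self.mode = mode
        self.atlases = atlases
        self.clip_side = clip_side
        self.clip_length = clip_length
        self.clip_stride = clip_stride
        self.window_volumes = window_volumes
        self.step_volumes = step_volumes
        self.L_override = L_override
        self.eval_stride = eval_stride
        self.val_stride = val_stride
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.grad_clip = grad_clip
        self.warmup_epochs = warmup_epochs
        self.seed = seed

    # -- construction -------------------------------------------------------

    def _build(self, records: list[SubjectRecord], rng: np.random.Generator):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        backbone_cfg = self.backbone_cfg or BackboneConfig()
        dfc_cfg = self.dfc_cfg or DfcEncoderConfig()
        atlas_order = self.atlases or sorted(records[0].series)
        self.atlas_order_ = list(atlas_order)
        self.n_frames_ = (self.L_override if self.L_override is not None
                          else aligned_length(self.clip_length, self.clip_stride,
                                              self.step_volumes))
        clip_shape = (self.clip_side,) * 3 + (self.clip_length,)
        self.backbone_ = None
        self.dfc_encoder_ = None
        self.head_vox_ = None
        self.head_dfc_ = None
        if self.mode != "dfc_only":
            self.backbone_ = VoxelTransformer4D(backbone_cfg, clip_shape, rng)
            self.head_vox_ = nn.Linear(backbone_cfg.embed_dim, 2, rng)
            self.head_vox_.weight.data[:] = 0.0  # logits start at 0 (loss ln 2)
        if self.mode != "voxel_only":
            rois = {a: records[0].series[a].n_rois for a in atlas_order}
            self.dfc_encoder_ = MultiAtlasDfcEncoder(rois, self.n_frames_,
                                                     dfc_cfg, rng)
            self.head_dfc_ = nn.Linear(dfc_cfg.fused_dim, 2, rng)
            self.head_dfc_.weight.data[:] = 0.0
        self.beta_ = nn.Parameter(np.zeros(()))  # alpha starts at 1/2

    def _modules(self):
        return [m for m in (self.backbone_, self.head_vox_,
                            self.dfc_encoder_, self.head_dfc_) if m is not None]

    def _trainable(self):
        params = []
        for m in self._modules():
            params.extend(m.parameters())
        if self.mode == "full":
            params.append(self.beta_)  # frozen in fixed_fusion
        return params

    # -- forward ------------------------------------------------------------

    @staticmethod
    def _normalize_clip(data: np.ndarray) -> np.ndarray:
        x = np.asarray(data, dtype=np.float64)
        sd = x.std()
        return (x - x.mean()) / (sd if sd > 0 else 1.0)

    def _forward(self, records: list[SubjectRecord], t0s: list[int],
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        """Fused logits [B, 2] for one clip per record."""
        z_vox = z_dfc = None
        if self.backbone_ is not None:
            clips = np.stack([
                self._normalize_clip(
                    sample_clip(r.bold, t0, self.clip_length, self.clip_stride,
                                self.clip_side).data)
                for r, t0 in zip(records, t0s)
            ])
            z_vox = self.head_vox_(self.backbone_(clips, drop_rng=drop_rng))
        if self.dfc_encoder_ is not None:
            bundle = {}
            for atlas in self.atlas_order_:
                frames = []
                for r, t0 in zip(records, t0s):
                    aligned = dfc_bundle(r.dfc, t0, self.clip_length,
                                         self.clip_stride,
                                         L_override=self.L_override,
                                         atlases=[atlas])[atlas]
                    frames.append(aligned.data)
                bundle[atlas] = np.stack(frames)
            z_dfc = self.head_dfc_(self.dfc_encoder_(bundle, drop_rng=drop_rng))
        if self.mode == "voxel_only":
            return z_vox
        if self.mode == "dfc_only":
            return z_dfc
        if self.mode == "fixed_fusion":
            return nn.scale(z_vox, 0.5) + nn.scale(z_dfc, 0.5)
        alpha = nn.sigmoid(self.beta_)
        return nn.mul(z_vox, alpha) + nn.mul(z_dfc, nn.sub(1.0, alpha))

    def _clip_logits(self, record: SubjectRecord, t0s: list[int]) -> np.ndarray:
        """Per-clip fused logits for one subject (no gradient tape)."""
        reps = [record] * len(t0s)
        return self._forward(reps, t0s).data

    # -- training -----------------------------------------------------------

    def fit(self, records: list[SubjectRecord], y=None):
        records = list(records)
        if y is not None:
            y = np.asarray(y, dtype=int)
            if len(y) != len(records):
                raise ValueError("y length does not match records")
        else:
            y = np.array([r.label for r in records], dtype=int)
        labels = {r.subject_id: int(c) for r, c in zip(records, y)}
        self.classes_ = np.array([0, 1])

        prepare_dfc(records, DfcParams(self.window_volumes, self.step_volumes))
        seq = np.random.SeedSequence(self.seed)
        init_ss, sample_ss, split_ss = seq.spawn(3)
        self._build(records, np.random.default_rng(init_ss))
        sample_rng = np.random.default_rng(sample_ss)

        # stratified validation split from the training subjects
        k_val = max(2, int(round(1.0 / self.val_fraction)))
        pheno = phenotype_frame(records)
        split = stratified_subject_folds(pheno, k_val,
                                         seed=int(split_ss.generate_state(1)[0] % 2**31))
        val_ids = set(split.subjects(0))
        train_recs = [r for r in records if r.subject_id not in val_ids]
        val_recs = [r for r in records if r.subject_id in val_ids]
        if not train_recs or not val_recs:
            raise ValueError("empty training or validation split")

        optimizer = nn.AdamW(self._trainable(), lr=self.lr,
                             weight_decay=self.weight_decay)
        history = []
        best_val = np.inf
        best_state = None
        best_epoch = -1
        for epoch in range(self.max_epochs):
            if self.warmup_epochs and epoch < self.warmup_epochs:
                optimizer.lr = self.lr * (epoch + 1) / self.warmup_epochs
            else:
                optimizer.lr = self.lr
            order = sample_rng.permutation(len(train_recs))
            t0s = {r.subject_id: random_clip_start(r.bold.n_volumes,
                                                   self.clip_length,
                                                   self.clip_stride, sample_rng)
                   for r in train_recs}
            epoch_losses = []
            for start in range(0, len(order), self.batch_size):
                batch = [train_recs[i] for i in order[start:start + self.batch_size]]
                onehot = np.eye(2)[[labels[r.subject_id] for r in batch]]
                logits = self._forward(batch, [t0s[r.subject_id] for r in batch],
                                       drop_rng=sample_rng)
                loss = nn.softmax_cross_entropy(logits, onehot)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; last batch "
                        f"{[r.subject_id for r in batch]}"
                    )
                optimizer.zero_grad()
                loss.backward()
                if self.grad_clip:
                    norm = np.sqrt(sum(float((p.grad**2).sum())
                                       for p in optimizer.params
                                       if p.grad is not None))
                    if norm > self.grad_clip:
                        for p in optimizer.params:
                            if p.grad is not None:
                                p.grad *= self.grad_clip / norm
                optimizer.step()
                epoch_losses.append(float(loss.data))
            val_loss = self._validation_loss(val_recs, labels)
            history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                            "val_loss": val_loss})
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_epoch = epoch
                best_state = self._capture_state()
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            self._restore_state(best_state)
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        self.best_val_loss_ = float(best_val)
        self.alpha_ = float(1.0 / (1.0 + np.exp(-self.beta_.data)))
        return self

    def _validation_loss(self, val_recs, labels) -> float:
        # one batched forward over all (subject, clip) pairs
        reps, t0s, ys = [], [], []
        for r in val_recs:
            starts = enumerate_clip_starts(r.bold.n_volumes, self.clip_length,
                                           self.clip_stride, self.val_stride)
            reps.extend([r] * len(starts))
            t0s.extend(starts)
            ys.extend([labels[r.subject_id]] * len(starts))
        logits = self._forward(reps, t0s).data
        return classification_loss(logits, np.eye(2)[ys])

    def _capture_state(self):
        return ([p.data.copy() for p in self._trainable()],
                self.beta_.data.copy())

    def _restore_state(self, state):
        arrays, beta = state
        for p, arr in zip(self._trainable(), arrays):
            p.data = arr.copy()
        self.beta_.data = beta.copy()

    # -- prediction ---------------------------------------------------------

    def predict_subject(self, record: SubjectRecord
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Subject-level class probabilities and the per-clip fused logits.

        Fused logits are averaged over the evaluation clip grid, then
        softmaxed (order-invariant, variance-reducing aggregation).
        """
        self._check_ready(record)
        starts = enumerate_clip_starts(record.bold.n_volumes, self.clip_length,
                                       self.clip_stride, self.eval_stride)
        per_clip = self._clip_logits(record, starts)
        probs = softmax_probs(per_clip.mean(axis=0))
        return probs, per_clip

    def _check_ready(self, record: SubjectRecord) -> None:
        if not hasattr(self, "classes_"):
            raise RuntimeError("classifier is not fitted")
        if self.dfc_encoder_ is not None and not record.dfc:
            prepare_dfc([record], DfcParams(self.window_volumes, self.step_volumes))

    def predict_proba(self, records: list[SubjectRecord]) -> np.ndarray:
        return np.stack([self.predict_subject(r)[0] for r in records])

    def predict(self, records: list[SubjectRecord]) -> np.ndarray:
        return self.predict_proba(records).argmax(axis=1)

    def score(self, records: list[SubjectRecord], y=None) -> float:
        y = np.array([r.label for r in records]) if y is None else np.asarray(y)
        return float((self.predict(records) == y).mean())

    # -- persistence --------------------------------------------------------

    def save(self, prefix) -> None:
        """Write weights (.npz) and config (.json) under ``prefix``."""
        prefix = Path(prefix)
        arrays = {}
        for mi, module in enumerate(self._modules()):
            for pi, arr in enumerate(module.state_dict()):
                arrays[f"m{mi}_p{pi}"] = arr
        arrays["beta"] = self.beta_.data
        np.savez(prefix.with_suffix(".npz"), **arrays)
        cfg = self.get_params()
        cfg["backbone_cfg"] = asdict(cfg["backbone_cfg"]) if cfg["backbone_cfg"] else None
        cfg["dfc_cfg"] = asdict(cfg["dfc_cfg"]) if cfg["dfc_cfg"] else None
        meta = {"params": cfg, "atlas_order": self.atlas_order_,
                "atlas_rois": {a: self.dfc_encoder_.encoders[a].n_rois
                               for a in self.atlas_order_} if self.dfc_encoder_ else {}}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, prefix, records: list[SubjectRecord]) -> "GatedFusionClassifier":
        """Rebuild a fitted classifier from ``save`` output; ``records``
        supply the atlas geometry for module construction."""
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        params = meta["params"]
        if params["backbone_cfg"]:
            bc = params["backbone_cfg"]
            for key in ("spatial_patch", "window_size"):
                bc[key] = tuple(bc[key])
            params["backbone_cfg"] = BackboneConfig(**bc)
        if params["dfc_cfg"]:
            params["dfc_cfg"] = DfcEncoderConfig(**params["dfc_cfg"])
        clf = cls(**params)
        clf.classes_ = np.array([0, 1])
        clf._build(records, np.random.default_rng(params["seed"]))
        with np.load(prefix.with_suffix(".npz")) as f:
            for mi, module in enumerate(clf._modules()):
                state = []
                pi = 0
                while f"m{mi}_p{pi}" in f:
                    state.append(f[f"m{mi}_p{pi}"])
                    pi += 1
                module.load_state(state)
            clf.beta_.data = np.asarray(f["beta"])
        clf.alpha_ = float(1.0 / (1.0 + np.exp(-clf.beta_.data)))
        return clf


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def cross_validate(estimator: GatedFusionClassifier,
                   records: list[SubjectRecord], k: int = 5, seed: int = 0,
                   keep_models: bool = False) -> dict:
    """Subject-wise stratified k-fold CV of a prototype estimator.

    Each fold clones the prototype (fresh weights, fold-specific seed),
    trains on the training folds and evaluates subject-level metrics on the
    held-out fold.  Returns fold metrics, per-subject probabilities, the
    fold assignment and (optionally) the trained per-fold models.
    """
    pheno = phenotype_frame(records)
    folds = stratified_subject_folds(pheno, k, seed)
    by_id = {r.subject_id: r for r in records}
    fold_rows, prob_rows, models = [], [], []
    for fold in range(k):
        train = [by_id[s] for s in folds.train_subjects(fold)]
        test = [by_id[s] for s in folds.subjects(fold)]
        clf = copy.deepcopy(estimator)
        clf.set_params(seed=seed * 1000 + fold)
        clf.fit(train)
        probs = clf.predict_proba(test)[:, 1]
        y = np.array([r.label for r in test])
        metrics = evaluate_predictions(y, probs)
        fold_rows.append({"fold": fold, **metrics,
                          "alpha": clf.alpha_, "epochs": clf.n_epochs_})
        for r, p in zip(test, probs):
            prob_rows.append({"subject_id": r.subject_id, "fold": fold,
                              "label": r.label, "prob_asd": float(p)})
        models.append(clf if keep_models else None)
    return {
        "folds": folds,
        "metrics": pd.DataFrame(fold_rows),
        "probabilities": pd.DataFrame(prob_rows),
        "models": models,
    }
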
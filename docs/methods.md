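# Methods

This note documents the models, numerical choices and limitations of
`fmrifuse`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Representations

**Clips.** A training/evaluation instance is a fixed-size voxel clip: start
index `t0`, length `T` volumes, within-clip stride `δ`, each frame
symmetrically zero-padded or center-cropped to a cubic side (extra voxel on
the high-index side when a deficit is odd, a fixed deterministic
convention). Indexing is 0-based half-open throughout; published 1-based
window formulas are translated at the formula sites.

**dFC.** Regional series are ROI means of voxel signals. Sliding-window
connectivity uses Pearson correlation — the standard sliding-window dFC
estimator — over windows `[kS, kS+W)`; zero-variance ROIs within a window
yield 0 off-diagonal and 1 on the diagonal (finite tensors, "no evidence of
coupling") plus a warning. Temporal alignment of the dFC subsequence to a
clip uses `k0 = ⌊t0/S⌋` and `L = ⌈Tδ/S⌉`: floor for a start index and
ceiling for a covering length are the only bracket choices for which the
aligned windows' volume span provably contains the clip span whenever no
end-of-scan padding occurred (a property test asserts this). Frames past
the last available window are zero-padded and counted; no padding mask is
passed to the encoder — padded frames contribute bias-only tokens.

## Encoders

**Voxel branch.** 4D patchification (non-overlapping `pz×py×px×pt`
patches, row-major token order over the `(nz,ny,nx,nt)` grid), a learnable
positional table, and pre-norm transformer blocks whose attention is
restricted to local 4D windows. Odd-indexed blocks cyclically shift the
grid by half a window per axis; token pairs separated by a wrap seam are
masked (additive −1e9 before softmax). Axes whose window already spans the
whole grid are never shifted. The published description fixes only
"window-based self-attention with MLP and residual connections"; the
pre-norm residual layout with alternating half-window shifts is the
minimal-assumption member of that family. No hierarchical patch merging is
performed. The clip embedding is the token mean.

**dFC branch.** Per atlas, each aligned frame is cut into `P×P` patches
(the frame is zero-padded on the high side to the next multiple of `P`
when `P ∤ Na` — this preserves every matrix entry, and all-zero patches
produce bias-only tokens), flattened and projected by atlas-specific
weights; tokens from all `L` frames form one sequence with learnable
positions, processed by full-attention transformer blocks and averaged.
Atlas encoders share no parameters. Fusion across atlases is concatenation
in a fixed atlas order followed by a learnable linear map — the simplest
learnable operator with the required signature; gated or attention-based
atlas fusion is deliberately out of scope.

**ROI-token mode.** Attribution needs ROI-indexed tokens, but the
classification tokenizer works on `P×P` patches. `roi_token_mode` replaces
the tokenizer with one token per ROI per frame (the projected ROI row of
the connectivity frame). This is the package's explicit reconstruction of
how patch-token attention maps to ROI-level attention — a design gap in the
published description, resolved here rather than guessed at. Classification
defaults to patch mode; the reference study trains in ROI-token mode so
that attribution operates on the very model that was trained.

## Fusion, training, evaluation

Two linear heads map the branch embeddings to 2-class logits; the fused
logit is `z = σ(β)·z_vox + (1−σ(β))·z_dfc` with trainable scalar `β`
initialized at 0 (unbiased ½–½ blend). Ablation modes: dFC-only,
voxel-only, and a fixed ½–½ blend with `β` frozen and excluded from the
optimizer. Training minimizes softmax cross-entropy with AdamW
(reference setting lr 1e-4, weight decay 0.01, batch 16). Two standard
stabilizers are used: classification heads are zero-initialized (initial
logits exactly 0, loss exactly ln 2, well-scaled first gradients) and the
global gradient norm is clipped at 1.0, with a short linear lr warmup.

One random valid clip start per subject per epoch serves as data
augmentation without changing epoch length. Validation subjects (20% of
the training fold, stratified identically) provide early stopping on
validation loss (default patience 10; best weights restored). Subject-level
prediction averages fused logits over a uniform clip-start grid
(`eval_stride` 10 volumes) and softmaxes the mean — order-invariant and
variance-reducing; the clip→subject aggregation rule is otherwise
unspecified in the source description.

Cross-validation is subject-wise and jointly stratified on diagnosis and
acquisition site: (diagnosis, site) strata are shuffled with the fold seed
and dealt round-robin from a random starting fold, so per-stratum fold
counts differ by at most one. Metrics are subject-level accuracy,
precision, F1 and AUC (Mann–Whitney rank statistic, midranks on ties; NaN
with a warning for single-class folds). ASD is the positive class
(`DX_GROUP = 1` in the ABIDE-style phenotype convention). The site-only
baseline fits a logistic regression from one-hot site identity under the
same folds — a sanity check that classification performance is not
explained by site alone.

## Attribution

For correctly classified subjects (default: correctly classified ASD
subjects; `who="all"` widens to all correctly classified, both readings of
the published subject set are exposed), ROI features are final-layer
ROI tokens averaged over evaluation clips and frames; ROI attention is the
final block's attention averaged over clips, heads and frame pairs, then
renormalized row-stochastic. `Score(r)` multiplies the feature norm by the
attention column sum (self-term included, as the printed sum runs over all
sources). The symmetrized subject-averaged attention matrix restricted to
the top-k ROIs (ties broken by ascending ROI index) is written as BrainNet
Viewer `.node`/`.edge` text files. Attribution runs per atlas; scores are
never pooled across atlases.

## The autodiff engine

No tensor/autodiff library is part of the package's dependency footprint;
`fmrifuse.nn` implements a small reverse-mode engine on numpy arrays
(broadcasted arithmetic, batched matmul, reshape/transpose/roll/concat,
softmax with additive masks, layer norm, ReLU/GELU/sigmoid, fused softmax
cross-entropy) plus AdamW with decoupled weight decay applied only to
matrix weights. Every primitive and the assembled blocks are
gradient-checked against central differences in the test suite. Ops whose
inputs carry no gradient short-circuit to constants, so inference builds no
tape. All computation is float64; with fixed seeds the whole pipeline is
bitwise reproducible. The MLP uses ReLU: at these model sizes on CPU the
GELU transcendental dominates the forward pass, and at depth ≤ 4 the
activation choice is immaterial.

## Synthetic cohorts

The generator emulates exactly the structure the method claims to exploit:
ROI-organized BOLD whose class difference is a *time-varying* coupling.
The first atlas spec is the generator parcellation; its latent ROI signals
are AR(1) (coefficient 0.3) driven by unit-variance innovations. During
"on" half-periods of `switch_period` volumes, each configured ROI pair's
innovations are correlated (`base_rho` for controls, `base_rho + delta_rho`
for cases); off half-periods are uncorrelated. Block switching — rather
than smooth drift — makes the dynamic signal unambiguous for sliding
windows and gives closed-form Monte-Carlo targets (on-window correlation ≈
the configured ρ; all-window class difference ≈ `delta_rho/2`). Voxels
carry their ROI latent plus a per-site constant offset and white noise.
The other atlases are independent Voronoi parcellations of the same volume,
so their regional series are mixtures of latent signals (parcellation
mismatch, as with real atlases). Sites are class-balanced by construction,
so site identity is uninformative unless the caller skews it.

Not emulated: hemodynamic response, drift, motion, spatial autocorrelation
of noise, realistic demographic distributions. Passing tests therefore
demonstrate that the pipeline recovers dynamic-coupling class structure
under controlled conditions — not performance on acquisition data.

## Reference study sizes

The reference study (tests and acceptance script) uses 60 subjects, 24³
voxels, 240 volumes, three atlases (12/10/16 ROIs), coupled pairs
(0,1) and (2,3), `delta_rho` 0.6, `switch_period` 30 volumes, site offset
sd 0.5, observation noise sd 1.0 — sizes chosen so a full 5-fold run takes
minutes on a single CPU while keeping ≥ 35 training subjects per fold. The
model is reduced accordingly: 16-dim depth-1 voxel backbone, 32-dim
depth-1 dFC encoders in ROI-token mode, dropout 0.1 on attention and
residual branches plus 0.1 dropout on raw connectivity entries (denoising
augmentation that discourages reliance on a single copy of a symmetric
entry), lr 2e-3 (a ~10³-step regime needs a larger step size than the
acquisition-scale reference of 1e-4), batch 8, patience 40. The voxel
backbone is kept deliberately tiny because the synthetic class signal
lives purely in ROI coupling: a larger backbone contributes no
information, only logit noise that slows the joint objective's
convergence. On this protocol the gate stays near α ≈ ½, consistent with
one branch carrying all class information and the other none.

## Attribution identifiability at small scale

The norm × attention-inflow score assumes that a trained model expresses
a region's importance through (i) the magnitude of that region's token
feature and (ii) the attention it receives. On the scaled-down reference
study this assumption holds only partially, for reasons worth recording:

* **Sparse reliance on redundant evidence.** Each coupled correlation
  entry appears in two symmetric rows of the connectivity frame, and both
  injected pairs separately suffice for perfect classification. A freely
  trained model often reads one copy and one pair; the score then
  correctly reports the model's reliance, which is a strict subset of the
  generative ground truth. Entry-level dropout counteracts this but does
  not eliminate it.
* **Register tokens.** Pre-norm transformers are known to repurpose
  low-information tokens as high-norm computation registers; these inflate
  feature norms of uninformative ROIs. The encoder exposes dedicated
  learnable register tokens (`n_registers`, excluded from attribution) as
  a mitigation.
* **Norm/attention anti-alignment.** Tokens that attention reads heavily
  tend to end with *small* residual-stream norms (their content is copied
  elsewhere), so the two factors of the score can rank different subsets
  of the truly informative regions.

In practice the coupled ROIs occupy most, but not always all, of the
top-k score positions, and which member of a redundant pair is ranked
lower varies across folds. Attribution results on this package should
therefore be read the way the attention-based-saliency literature advises:
as the model's reliance pattern, not as an exhaustive recovery of every
ground-truth region.

## Known limitations

* Sliding-window Pearson is the only dFC estimator (no tapering, DCC or
  state-switching models).
* The encoder receives no padding mask; heavily padded aligned sequences
  (clips near scan end) contribute diluted evidence.
* Attention-based scores are indicative, not causal; the attribution layer
  (final block) and head/time averaging are fixed conventions.
* `L_override`, when set, silently wins over coverage-matching length
  (logged); precedence between the two published definitions is otherwise
  undefined.
* CPU-only: the engine favors clarity and testability over throughput;
  acquisition-scale inputs (96³×20 clips, 100+ ROI atlases) are supported
  by configuration but not by the included compute budget.
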
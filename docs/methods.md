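# Methods

`sinusct` models the structural analysis of paranasal-sinus CT as a chain of
five learned or rule-based stages, exercised end to end on procedurally
generated sinus phantoms.  This note records the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## The phantom generator

Real sinus CT is highly variable: four paired air-filled cavities
(maxillary, ethmoid, frontal, sphenoid) of subject-specific pneumatization,
imaged on different scanners at different slice thicknesses.  The generator
(`sinusct.phantoms`) reproduces the *structure* of this problem while
keeping the geometry analytically known:

- A head is an ellipsoid of soft tissue (40 HU) wrapped in a bony shell
  (700 HU) on an air background (-1000 HU); head semi-axes are 0.46 of the
  grid extent.
- Eight cavities (four bilateral pairs) are ellipsoids of air with a thin
  bony wall, placed at fixed anatomically inspired relative centres:
  maxillary lateral-inferior, ethmoid central (subdivided into
  `ethmoid_cells` sub-cells by 1-voxel bone septations), frontal
  superior-anterior, sphenoid posterior-central.  Labels 1-4 mark cavity
  interiors; septa are bone, not cavity.
- Scanner variability is emulated by per-scan Gaussian noise (SD drawn from
  2-10 HU), Gaussian blur (sigma 0.2-0.8 voxels) and a global intensity
  shift (-25 to +25 HU), applied in that order after geometry is rendered.
- Four insertable anomalies, applied to one seeded randomly chosen cavity:
  `wall_thickening` lines the cavity interior with a soft-tissue rind
  (depth 0.45 x strength of the local radius), `partial_opacification`
  fills the inferior fraction = strength of the cavity with fluid (30 HU,
  gravity-dependent level), `total_opacification` fills it completely, and
  `asymmetry` shrinks one side's cavity radii by (1 - strength).  Anomaly
  ground truth is a separate binary mask; labels keep marking the anatomical
  cavity for opacification (content changed, anatomy unchanged) and follow
  the shrunken geometry for asymmetry (anatomy changed).

All randomness derives from one integer seed through
`numpy.random.SeedSequence` spawning, so any cohort is reproducible and
per-sample streams are independent.

What the phantoms do **not** emulate: anatomical shape variability between
subjects (cavity centres and radii are fixed up to `cavity_scale`), partial
volume effects at sub-voxel walls, beam hardening, metal artifacts, and any
pathology beyond the four stylized anomalies.  Consequently the
segmentation task is easier than on real data — geometry can be memorized —
and the reported Dice values characterize the pipeline's correctness and
trainability, not clinical performance.

## Preprocessing

The harmonization chain is: replace non-finite voxels with zero; resample
to isotropic spacing (1 mm default; trilinear for intensities, nearest for
labels, output shape `round(shape * spacing / target)` per axis);
standardize the grid shape by center-cropping oversized axes and
symmetrically zero-padding undersized ones (odd differences put the extra
voxel on the high-index side); min-max normalize a fixed HU window onto
[0, 1].  The window default is (-1000, 2000) HU rather than per-volume
extremes, because per-volume extremes are scanner artifacts and a fixed
window actually removes inter-scanner intensity variability.

Background suppression uses a -500 HU threshold, but as a *body mask*: the
largest 6-connected supra-threshold component with interior holes filled.
Zeroing sub-threshold voxels directly would destroy the air-filled sinuses
(-1000 HU), which are the object of study; hole filling keeps them inside
the retained region.  Cropping is mask-guided: the tight bounding box of a
mask dilated by a margin, clamped to the grid.

Augmentation is intensity-only (gamma in [0.9, 1.1], scale in
[0.95, 1.05] during segmenter training): geometric augmentation would
distort the thin bony walls that segmentation must delineate, and masks are
never modified.

## Hybrid segmenter

The segmenter is a U-shaped encoder-decoder.  A full-resolution stem conv
feeds a strided patch embedding; four hierarchical stages then alternate
windowed multi-head self-attention blocks (shift 0 and window/2 cyclic
shift on alternating blocks, wraparound masking so tokens from different
original windows never attend to each other, LayerNorm + MLP as usual) with
a residual 3x3x3 convolution block under group normalization, downsampling
between stages by strided conv.  The decoder mirrors with k=2, s=2
transposed convolutions, stage-wise skip connections (concatenate, 1x1x1
fuse, 3x3x3 refine) and a final expansion back to full resolution where the
stem features are fused before a 1x1x1 classification head.

Two profiles are registered:

| parameter | full-scale | desk |
| --- | --- | --- |
| input | 96^3 | 48^3 |
| embed dim | 48 | 24 |
| depths | (2,2,6,2) | (1,1,2,1) |
| heads | (3,6,12,24) | (1,2,4,8) |
| window | 7^3 | 3^3 |
| conv ladder | (32,64,128,256) | stage widths |
| patch stride | 2 | 4 |
| convs per residual block | 2 | 1 |
| MLP ratio | 4 | 2 |
| optimizer | AdamW 1e-4, cosine, batch 2, 200 epochs | AdamW 3e-3, cosine, batch 2, 30 epochs |

The desk profile is sized so the whole training run is a few minutes on one
CPU core; the coarser patch stride is compensated by the stem skip so the
head still predicts at full resolution.  Window attention pads token grids
up to window multiples internally and masks the padding, so the 7^3 window
works with the 96^3 profile's 48/24/12/6 stage resolutions.

Ablation variants are pure configuration: `cnn_only` drops the attention
blocks (the conv path remains), `transformer_only` drops the interleaved
conv blocks; both have strictly fewer parameters than `full`.

The loss is an equal-weight (0.5/0.5) sum of soft Dice over the four
foreground classes (smoothing constant 1e-5 in numerator and denominator,
so an absent class contributes a perfect score instead of an indeterminate
one) and voxel-wise cross-entropy (probability floored at 1e-12 inside the
log).  Pseudo-labelled samples, when present, multiply their per-sample
loss by `pseudo_label_weight`; at weight 0 they contribute exactly zero
gradient.  Whole-volume inference tiles with 50% overlap and mean-blends
probabilities; argmax ties break toward the lower class index.

## Convolutional autoencoder and residual maps

The CAE encodes a normalized sinus-region crop through three stride-2
convolutions into a dense latent bottleneck and decodes through symmetric
transposed convolutions to a logistic (hence [0, 1]-bounded) reconstruction.
Reference scale: 64^3 input, filters (32, 64, 128), latent 256; desk scale:
32^3, (8, 16, 32), latent 64.  Training uses Adam at 1e-3, batch 4, with a
step decay of x0.1 every 50 epochs.  The default reconstruction loss is L2;
L1 is available by configuration (the two appear interchangeably in
descriptions of this architecture family; the choice is surfaced, not
hidden).

Training inputs are sinus-bounding-box crops (margin 2 voxels), not whole
heads: the model should spend its capacity on sinus morphology.  The
training API refuses any sample not flagged anomaly-free — the entire
premise of residual anomaly mapping is that the model has only ever seen
the healthy manifold.  At inference the residual map is r = |x - x_hat|,
returned together with the reconstruction and the latent code.

Anomaly localization is quantified as a contrast ratio: mean residual
inside the anomaly ground truth over mean residual in the labeled sinus
voxels outside it (infinity flagged when the reference mean is exactly
zero).  At desk scale (16 normal training phantoms, 60 epochs) the median
contrast over 16 anomalous held-out phantoms is ~2.5-3.5, against a sham
median of ~0.6-0.8 for random sinus sub-regions in all-normal controls.
Wall thickening is the subtlest anomaly (soft-tissue rind adjacent to an
already-soft wall) and produces the lowest contrasts.

## Fused structural embeddings

The feature extractor consumes a three-channel stack: normalized CT,
segmentation mask scaled by /4 onto {0, .25, .5, .75, 1}, and the residual
map clipped at its own 99th percentile and scaled to [0, 1] (robust to the
heavy residual tail).  Three 3x3x3 conv + max-pool blocks (32/64/128
filters), global average pooling, and a 64-unit dense layer with dropout
0.3 produce the embedding.  Channel ablations (`no_residual`, `no_mask`)
zero a channel in place, preserving shape.

Because no pathology labels exist, training is self-supervised: a 4-scalar
head regresses the mean residual inside each sinus compartment
(zero-initialized, so an untrained head predicts exactly 0 and yields an
exactly-zero Grad-CAM).  This pretext is label-free and gives Grad-CAM a
differentiable scalar target, but it has a known limitation recorded here
deliberately: the normal-cohort component of the target (the reconstruction
noise floor) is a scanner-level property predictable from anywhere in the
crop, so the task only weakly forces spatially sinus-specific features.
The embedding separation between normal and anomalous phantoms (silhouette)
is therefore positive but small at desk scale, and the Grad-CAM sinus
enrichment hovers around its factor-2 target rather than clearing it
robustly.  Stronger pretexts (e.g., adding per-compartment intensity
regression) sharpened embeddings in side experiments but degraded CAM
localization, and were not adopted.

## Grad-CAM

For a chosen scalar target — default: the maximal pretext output, the
class-discriminative analog for a network without a classifier; optionally
a fixed sinus index — channel weights are the spatial mean of the target's
gradient at the final convolutional layer; the CAM is the rectified
weighted channel sum, trilinearly upsampled to the input geometry and
min-max normalized onto [0, 1], with an identically-zero map passed through
unchanged.  Localization is scored by the mass fraction of the CAM inside a
region, compared against the region's volume fraction (a uniform map scores
exactly the volume fraction).

## Evaluation metrics

Per foreground class: Dice 2|P∩G|/(|P|+|G|), Jaccard |P∩G|/|P∪G| (the
identity J = D/(2−D) is exact by construction), precision, recall.
Conventions: both masks empty scores 1 everywhere; exactly one empty scores
0 with the undefined ratio reported as 0.  HD95 is the 95th percentile
(linear interpolation between order statistics) of the *pooled*
bidirectional surface-distance multiset — symmetric by construction, and
exactly scale-equivariant in the voxel spacing.  Surface voxels are mask
voxels with at least one 6-connected face neighbour outside the mask, the
grid border counting as outside; distances are measured between
surface-voxel centres with no sub-voxel surface model, which keeps the
definition exactly reproducible by an exhaustive oracle.  Note that HD95
tools differ in all three choices (pooled vs max-of-directed percentile,
surface definition, interpolation); numbers are comparable only within one
convention.

## Numerical and engineering choices

All networks run on a small reverse-mode automatic-differentiation engine
over float32 numpy arrays (`sinusct.nn`): im2col convolutions backed by
BLAS, fused group/layer normalization backward passes, batched-matmul
attention.  Gradient correctness is pinned by central-difference tests.
Training is seeded end to end: a single pipeline seed derives per-stage
seeds via `SeedSequence`, identical runs reproduce loss histories to 1e-6
(CPU, fixed reduction order).  Dropout draws from its own stream so
evaluation-mode determinism is free.

Degenerate inputs are handled explicitly: all-NaN volumes sanitize to zero;
empty masks are rejected where an operation is undefined (cropping, HD95,
contrast ratios) with the reason in the error; a constant residual map
survives percentile scaling unchanged; argmax and component ties break
deterministically.

## Known limitations

- Phantom geometry is fixed across a cohort; only intensity statistics
  vary.  Segmentation Dice near 1 therefore demonstrates pipeline
  correctness and optimizer health, not robustness to anatomical
  variability.
- The desk segmenter profile differs from the full-scale profile in patch
  stride, block depth and MLP ratio (table above); conclusions about the
  full-scale architecture transfer only qualitatively.
- The pretext objective for the feature extractor is an implementation
  choice (the architecture family it follows does not fix one), and its
  global-shortcut weakness is documented above.
- Silhouette and CAM-enrichment outcomes at desk scale are marginal and
  seed-sensitive; the reported values are computed fresh per run rather
  than cached or tuned.
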
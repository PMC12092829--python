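# Methods

This note documents the models, algorithms and numerical choices in
`sbfseg`, what the synthetic phantoms do and do not emulate, and the
problem sizes used in the package's own experiments.

## Problem setting

A serial block-face (SBF) volume is a stack of sequential grayscale
cross-sections, indexed `(z, y, x)` with z the milling/acquisition
direction.  Voxels are anisotropic: the z spacing (slice thickness) is
typically coarser than the in-plane spacing.  Each voxel of a labeled
volume carries one of six classes: background (0), cytoplasm (1), plastid
(2), mitochondrion (3), peroxisome (4), nucleus (5).  *C. merolae* carries
exactly one organelle of each type, divides through five morphological
stages, and partitions each organelle to both daughters — which is why
late-stage volumes contain two connected components per organelle class.

## Preprocessing chain

Order: anisotropy correction → bilateral filter → cube resize →
normalization.  All geometric steps use the same nearest-neighbor operator
(output index `i` maps to input index `floor(i·n_in/n_out)`), so intensity
and label volumes transform identically and label classes are never
blended; nearest-neighbor also guarantees no new intensity values are
invented.  Normalization divides 8-bit values by 255.

The bilateral filter runs in 2D on each acquired section.  It averages a
square window of radius `ceil(3·σ_spatial)` with Gaussian spatial weights
and Gaussian intensity-difference weights, renormalized over the in-image
part of the window so borders are not darkened.  Defaults:
`σ_spatial = 2` voxels, `σ_range = 10%` of the dtype range.  These are
free parameters of the pipeline; flat fields are exact fixed points and
the output range is contained in the input range.  (A hand-rolled
implementation is used rather than `skimage.restoration.denoise_bilateral`
because the package's contracts — border renormalization, exact windowed
Gaussian limit as `σ_range → ∞` — depend on internals that library does
not guarantee.)

Reslicing is pure re-indexing: section `i` along y is `data[:, i, :]`.
It requires isotropic volumes (otherwise sections are geometrically
distorted) and is exactly invertible.  Tri-axial augmentation emits
`3 × side` paired intensity/label sections per cube; the three axis
streams are mixed uniformly during training.

## The scanning attention U-Net

The network is strictly 2D and is "scanned" through the volume section by
section; input is `[batch, 1, H, W]`.  Encoder: five channel levels
(`base·2^d`, d = 0..4) of paired same-padding 3×3 convolutions, each
followed by batch normalization and ReLU, with 2×2 max pooling between
levels.  Decoder: 2×2 transposed-convolution upsampling (halving
channels; nearest-neighbor + 1×1 convolution available via
`upsample_mode`), an additive attention gate on each skip connection, then
paired 3×3 convolutions on the concatenation.  The final layer is a 1×1
convolution to 6 channels with channel softmax and no batch
normalization.  At full scale (base 64, side 256) the layer schedule runs
64×256² down to 1024×16² and back, and the construction has 31.4 M
parameters.  (Published counts for comparable attention U-Nets vary
several-fold with the attention-gate and upsampling design, which layer
tables rarely pin down; this package reports the count of its own
construction.)

The attention gate projects the skip feature `x` and the upsampled coarser
decoder feature `g` to `C/2` channels with 1×1 convolutions, applies ReLU
to the sum, reduces to one channel, and multiplies `x` by the sigmoid of
the result — a learned spatial mask that suppresses irrelevant skip
content.

Everything — forward, backward, AdamW — is float32 NumPy.  Convolutions
are im2col + GEMM; the backward pass was verified against central finite
differences (worst relative error ~7e-7 in float64).  Weight
initialization is He-normal, seeded; batch normalization keeps running
statistics (momentum 0.1) for inference mode.

## Tversky loss

Per class `c`, on soft predictions summed over all pixels of the batch:

    TI_c = (TP_c + s) / (TP_c + α·FP_c + β·FN_c + s),  loss = mean_c (1 − TI_c)

Defaults `α = 0.3, β = 0.7` (penalizing false negatives, which protects
the small organelle classes) and smoothing `s = 1`.  The smoothing term
matters: without it a class absent from the truth scores index 0 until its
predicted mass is *exactly* zero — unreachable under softmax — which pins
the minimum attainable loss.  With `s > 0` the loss is still zero iff the
prediction equals the truth exactly, and `α = β = 0.5` is algebraically
the (equally smoothed) soft Dice loss.  `smooth=0` recovers the bare
formula, with an empty denominator scored as a perfect index.

Optimization: AdamW (decoupled weight decay 0.01), learning rate
`base · 0.95^epoch`.  Full-scale defaults are base 1e-5 and 5 epochs.

## Multi-directional inference and fusion

A 2D network's errors depend on the cutting direction, so inference runs
along z, y and x and the three probability volumes are reassembled onto
the common `(z, y, x)` grid.  Fusion takes, per voxel, the class holding
the single largest of the 18 probabilities; ties break to the lowest class
index, then to axis order z, y, x (implemented by class-major ordering
under NumPy's first-maximum rule, hence exactly reproducible).  An
alternative reading — majority vote of the three per-direction argmaxes —
coincides with this rule whenever two directions agree on the globally
maximal class; the global-argmax reading is implemented and per-voxel
disagreement counts are available via `direction_disagreement`.

A median filter on categorical labels is ill-defined, so denoising uses
the neighborhood mode over the `(2r+1)³` cube (default r = 1), clipped at
the volume border; ties keep the center voxel's label when it is among the
modes, else take the lowest class index.  Constant volumes are fixed
points.

## Evaluation

IoU per class is `|pred∩truth| / |pred∪truth|` on hard labels after
fusion.  An empty union makes the entry *undefined* (NaN), flagged and
excluded from averages rather than counted as zero — otherwise a
single-component stage would be punished for classes it cannot contain.
Split plans hold out one cell per division stage per case, with validation
cells disjoint across cases; a stage pool is degenerate only when it
contains a single cell (that case would have no training cell of the
stage), since validation cells of *other* cases still train the current
one.

## Cell extraction

The default foreground masker thresholds each z-section at the global Otsu
level of the (denoised) volume, then applies a 3×3 morphological opening
and fills 2D holes — dark organelles inside a cell stay cell.  Otsu
presumes a usable bimodal histogram: the pipeline expects denoised input
(the CLI runs the bilateral filter first), and a zero-contrast volume
yields an empty mask.  External maskers (e.g. a promptable 2D
segmentation model) plug in as any callable mapping a section to a boolean
mask; they are deliberately not a dependency.

Instances come from a 3D watershed on the negated Euclidean distance
transform, restricted to the mask, 26-connectivity.  Seeds are
distance-transform local maxima with a minimum mutual Euclidean separation
(`min_seed_distance`, default 18 voxels), enforced by explicit greedy
highest-first suppression per connected component — `peak_local_max` alone
keeps equal-height plateau peaks closer than `min_distance`, which would
split the two equally-deep lobes of a dividing cell.  The default
separation is approximately the full span of a mid-division scene cell:
half the expected *spherical* cell diameter would fall below the lobe-peak
separation of a dumbbell (~1.9× the lobe radius) and cut dividing cells in
two.  Each instance is cropped with a margin (default 2 voxels), the box
clamped to scene bounds, and voxels of other instances blanked to the
scene's median background intensity.

## Synthetic phantoms

A phantom cell is the union of two ellipsoids whose center separation
grows with the pinch parameter `c = (stage−1)/4`: coincident at stage 1, a
nearly-split dumbbell at stage 5.  The separation is capped at 0.95× the
lobe x-semi-axis so the mask always remains one connected component
(cytokinesis incomplete).  Organelles are ellipsoids placed by rejection
sampling inside an eroded cell core, kept out of 26-adjacency with each
other; stages 1–3 place one component per class, stages 4–5 two (the
second mirrored into the opposite lobe).  Default volume fractions:
plastid 0.22, nucleus 0.07, mitochondrion 0.05, peroxisome 0.015.

Intensities are class means plus Gaussian voxel noise (sd 8), clipped to
0–255: background 30, cytoplasm 105, plastid 200 (distinctly bright),
mitochondrion 45 and nucleus 55 (deliberately overlapping the background
noise band, as in the real data), peroxisome 70.  Optional slice-wise
gain jitter emulates section-to-section SEM variation (off by default).
Scenes place phantoms by bounding-sphere rejection sampling with a
guaranteed background gap and return instance ground truth.

Not emulated: SEM image formation physics (charging, curtaining), starch
granules as a confounder, textured organelle interiors, irregular
(non-ellipsoidal) peroxisome shapes, and cells touching each other.
Passing tests on phantoms therefore demonstrate that the pipeline's
machinery is correct and that its relative difficulty ordering matches the
intensity-overlap structure; they do not certify accuracy on real FIB-SEM
volumes.

## Desk-scale experiment sizes

The package's experiments (tests and `scripts/acceptance.py`) run a scaled
version of the full protocol chosen to fit a single CPU core:

* tiny network: base 8 channels, 64-voxel cubes, depth 5 (~0.49 M
  parameters);
* 20 training phantoms (4 per stage), 5 held-out (1 per stage, disjoint
  seed stream), tri-axial augmentation (3840 sections), 5 epochs over a
  reshuffled 960-section subsample per epoch, batch 8;
* base learning rate 1e-3 with the 0.95/epoch decay.  The full-scale
  base rate (1e-5) is matched to ~3×10⁵ optimizer steps; at ~3×10³ steps
  an equivalent optimization budget needs a proportionally larger rate,
  chosen once as part of the scale reduction;
* fusion study: 10 phantoms blurred along one axis (Gaussian σ = 2,
  cycling z/y/x), comparing per-direction and fused foreground IoU;
* extraction study: multi-cell scenes (96³, cells of radius 8, stages
  cycling) with 2–5 cells.

Architecture checks at full scale (base 64, side 256) are
construction-time only — no full-scale training is attempted.

## Known limitations

* CPU NumPy training is ~3 orders of magnitude slower than the GPU
  setting the architecture comes from; the package is a faithful,
  testable implementation, not a performance port.
* The smallest classes (peroxisome, nucleus) are often missed entirely at
  the tiny scale — consistent in *ordering* with published full-scale
  results, but not in absolute value.
* The Otsu masker fails on scenes whose foreground fraction is so small
  that the histogram loses bimodality before denoising; an external
  masker interface exists for such cases.
* Watershed seeding assumes cells are roughly convex up to one dumbbell
  neck; chains of more than two lobes would need a different seeding rule.
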
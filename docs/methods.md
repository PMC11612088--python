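# Methods

## Problem setting

Cervical lymph nodes on contrast-enhanced neck CT are small (the clinically
interesting ones measure 5–10 mm along their long axis), occupy well under 1%
of the voxels of a scan, appear on only a minority of axial slices, and are
easily confused — on any single slice — with small vessels of similar
attenuation.  The package implements a segmentation stack built around these
four facts: a phantom generator that reproduces them, two architectures (a
conventional attention-gated U-Net and a spatial context network designed for
small objects), an asymmetric composite objective, class-balanced training
regimes in 2D / 2.5D / 3D, and object-level evaluation that scores detection
per node rather than only per pixel.

## Phantom cohorts

`nodeseg.phantom` renders volumes of Gaussian soft-tissue background
(N(60, 15) HU-like by default) containing:

* **Nodes** — randomly rotated triaxial ellipsoids, long axis drawn uniformly
  from [5, 10] mm, short/long aspect ratios from [0.5, 0.8], intensity
  +40 HU over background by default.  Ellipsoids are voxelised at voxel
  centres, and the whole object intensity field is blurred (σ = 0.7 voxels)
  for partial-volume edges; the binary mask is the unblurred ellipsoid.
  Node placement retries until objects do not touch (bounded retries, then a
  placement error).  On axes thinner than the node the centre collapses to
  the mid-plane and the ellipsoid truncates at the boundary.
* **Vessels** — random-walk tubes spanning the volume in z, radius 1–2.5 mm,
  with the same contrast distribution as nodes by default.  They are rendered
  in the image but never labelled: they exist to punish slice-wise
  overcalling, which is the dominant failure mode for small-node
  segmentation.

Default cohort geometry is 48 axial slices of 96×96 voxels at 1 mm isotropic
spacing with 1–3 nodes per volume; measured over a cohort this yields ≈ 79%
node-free axial slices, matching the strong inter-slice class imbalance of
the target regime (more than 70% of slices empty).  Intensity statistics are
plausible for contrast-enhanced neck soft tissue but are free parameters of
the generator, not claims about any specific scanner.

What the phantoms do **not** emulate: anatomy (no nodal stations, no organs),
scanner physics (no beam hardening, no anisotropic spacing by default), and
pathology.  Passing tests on phantoms therefore demonstrates that the
algorithms are implemented correctly and can learn the intended statistical
structure — not clinical performance.

## Architectures

Both networks are rank-agnostic: the same topology is instantiated with 2D
operators for slices (1 input channel) and 2.5D stacks (15 channels), or 3D
operators for 96³ patches.  All convolution blocks are convolution + batch
normalisation + ReLU; convolutions inside blocks carry no bias (batch
normalisation would cancel it).  Channel widths start at a configurable base
(32 by default) and double per encoder stage.

**Attentional U-Net.**  Four conv+maxpool encoder stages (16× total
down-sampling), a bottleneck block, and three transposed-convolution decoder
stages.  Each decoder stage fuses its encoder skip through an additive
attention gate: decoder and encoder features are projected to a shared
P-dimensional space (P < C), summed, passed through ReLU and a 1×1
projection Ψ to a single channel, and squashed by a sigmoid into a gate map
H ∈ (0,1) that rescales the encoder feature before concatenation and 3×3
fusion.  A final 2× upsampling + 1×1 convolution restores input resolution.

**Spatial context network (SNet).**  Only two down-sampling stages (4×
total), then two convolutions that double the channel depth at constant
resolution.  The limited receptive field is recovered by a dense atrous
spatial pyramid: four 3×3 dilated convolutions with dilations 3, 6, 9, 12,
where each stage's output is concatenated onto its input before the next
stage (so stage k sees c₀ + (k−1)·g channels), followed by a 1×1 reduction
to the multi-scale context feature F_M.  Padding equals dilation, so spatial
shape is preserved exactly throughout the pyramid.

The decoder has two levels, each applying **reverse axial attention (RAA)**
between the upsampled decoder feature D and the encoder skip E:

* axial attention on E: self-attention factorised into 1D passes along each
  spatial axis (A = softmax(QKᵀ/√d_k), output = A·V, with Q/K/V from 1×1
  convolutions; single head, d_k = max(C/8, 8));
* a reverse gate 1 − sigmoid(conv₁ₓ₁(D)), which suppresses regions the
  decoder already calls foreground so attention mass concentrates on residual
  structure;
* the gated attention output ("filtered feature") yields a 1-channel partial
  heatmap via 1×1 convolution, and is concatenated with D and fused by a 3×3
  block to form the level output.  Feeding the filtered feature into the
  fusion (rather than supervising it in isolation) lets the reverse-attention
  branch influence the final prediction directly; this was a genuinely open
  design point and is the package's choice.

Both partial heatmaps are upsampled (nearest-neighbour) to input resolution
and supervised against the ground truth.  Both networks initialise the final
1×1 head bias to −2 so that initial predictions are near-empty; with <1%
foreground this avoids spending the first epochs unwinding a sea of false
positives.

Optional auxiliary heads on the SNet: a slice-level classification logit
(global average pool of the deepest encoder feature + linear layer) and a
localization heatmap (1×1 convolution on F_M at 1/4 resolution) regressed
against Gaussian node-centre targets (σ = 3 px at full resolution).  The
localization target is a design decision — a centre-heatmap is the minimal
differentiable localization formulation; a box-regression alternative would
be equally defensible.

## Objective

Final prediction: Tversky loss on soft counts,
L_T = 1 − (TP + s)/(TP + α·FP + β·FN + s), with TP = Σ p·g, FP = Σ p·(1−g),
FN = Σ (1−p)·g.  α = β = 0.5 reduces exactly to the soft Dice loss (verified
against an independent oracle to 1e-6).  Defaults α = 0.3, β = 0.7 penalise
missed foreground more than spurious foreground — the right asymmetry when
the object must not be missed — and are exposed in config.  Smoothing
s = 1e-6 makes the loss 0 on empty slices with empty predictions, the
dominant case here.

Partial heatmaps: structure loss = boundary-weighted IoU + boundary-weighted
BCE.  Pixel weights w = 1 + λ·|meanpool_k(g) − g| with λ = 5 and k = 31
(k = 15 for 96³ patches, where 31 would exceed a patch's useful extent);
w → 1 far from mask boundaries and grows where a k-neighbourhood straddles
one.  Weighted BCE is computed from logits with a stable softplus form;
weighted IoU is 1 − (Σ w·p·g + 1)/(Σ w·(p + g − p·g) + 1).

Total: L = L_T(final) + Σ_levels (L_IoU^w + L_BCE^w), all components
reported individually and summing exactly to the total.

## Training regimes

* **2D** — every axial slice is a sample; batches of 16 are exactly
  class-balanced (8 node-bearing + 8 node-free; the minority class is
  resampled with replacement each epoch).  Learning rate 5e-5.
* **2.5D** — identical, but each sample is the target slice with 7 preceding
  and 7 following slices as 15 input channels (edge slices replicate the
  boundary slice so the channel count never changes).  Batch 8, lr 5e-5.
* **3D** — one positive (≥1 foreground voxel, centred on a random foreground
  voxel with ±16-voxel jitter) and one negative (zero foreground,
  rejection-sampled) 96³ patch per volume per epoch; batch 8, lr 1e-4.
  Inference tiles the volume with 96³ windows at 0.5 overlap and blends
  overlapping predictions with a Gaussian importance map (σ = window/8)
  accumulated in float64; a single-tile volume reproduces the direct forward
  pass bitwise.

The optimizer is Adam with decoupled weight decay (1e-5).  Augmentation
(optional): 2D rotation within ±10°, vertical flip, brightness/contrast and
gamma jitter; 3D affine with rotation range (0, 0, π/15), per-axis scale
range 0.1, and intensity shift 0.1; geometric transforms are applied
identically to image (linear resampling) and mask (nearest neighbour).
Epoch count is capped at 100 with early stopping on validation Dice
(patience 15); model selection keeps the best-validation-Dice weights.
Validation Dice is pooled over all validation voxels rather than averaged
per slice, which is stable under the many empty slices.

All tensor computation runs on a reverse-mode automatic-differentiation
engine over numpy arrays written for this package (`nodeseg.nn`):
convolution is evaluated as one GEMM per kernel tap (flat memory for 3D),
and every operator's analytic gradient is verified against central finite
differences in the test suite.

## Evaluation

Pixel level: Dice and Jaccard (empty-vs-empty defined as 1; the identity
J = D/(2−D) is property-tested).  Object level: ground-truth nodes are 3D
connected components (26-connectivity); for slice-based models each slice a
node spans counts as detected when the prediction covers ≥ 80% of the node's
area on that slice (a node on 3 slices covered 0.9/0.85/0.6 scores 2/3), and
accurate-prediction / miss counts aggregate these slice-objects.  Volumetric
models apply the same 80% coverage rule to the node's full 3D extent.
"Overlap" is read as the covered fraction of the ground-truth object
(recall-like), which centres the node being found; a Dice ≥ 0.8 variant is
selectable.  Predictions are binarised at probability 0.5 (the sigmoid
midpoint) before scoring; both thresholds are exposed in config.

## Desk-scale study sizes

The shipped convergence study (`nodeseg.recipes`) uses 51 easy phantoms
(40 train / 10 val / 1 held out) of 12×64×64 voxels with node contrast
+150 HU and reduced vessel contrast (+40): at equal contrast a slice-wise
model cannot in principle distinguish a vessel cross-section from a node,
which is the realism feature of the default cohort, not a learnability
check.  The network is the SNet at base width 8 trained with balanced
batches of 16 for at most 30 epochs of 8 steps at learning rate 5e-3 (scaled
up from the clinical-scale 5e-5 in proportion to the much shorter
optimisation budget), stopping once validation Dice reaches 0.80.  Under
these conditions all of 5 seeds typically reach Dice ≥ 0.80 within ~7
epochs; the attentional U-Net under the identical budget also converges on
this easy cohort.  These sizes are the package's choice of a minimal
convincing demonstration; they are not estimates of clinical performance.

## Known limitations

* The phantom background is white noise; real CT background texture is
  spatially correlated.
  Networks may exploit this (nodes are the only smooth bright blobs), which
  is one reason the easy study converges quickly.
* The 2.5D and 3D regimes are implemented and tested but the shipped study
  trains the 2D regime only; volumetric training at meaningful sizes is
  outside a single-CPU budget.
* Auxiliary-task finetuning is demonstrated to beat chance on slice
  classification; no claim is made that it improves segmentation, mirroring
  the ambiguous value such heads have in this problem.
* The autodiff engine is single-threaded numpy; it is adequate for the
  shipped studies, not a GPU training framework.
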
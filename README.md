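# nodeseg

Detection and segmentation of **small lymph nodes (5–10 mm) on CT-like
volumes**.  Small nodes are the hard case of medical image segmentation:
they occupy well under 1% of the voxels of a scan, most axial slices contain
no node at all, and small vessels mimic them on any single slice.  This
package implements, end to end and fully testable on synthetic phantoms:

* a **spatial context network (SNet)** — a shallow encoder (only 4× total
  down-sampling, so small objects survive), a **dense atrous spatial
  pyramid** (dilated convolutions d = 3, 6, 9, 12 with forward
  concatenation) to recover receptive field without further down-sampling,
  and **reverse axial attention** decoder levels that gate factorised 1D
  self-attention with 1 − σ(decoder heatmap) so attention flows to
  not-yet-confident regions;
* an **attention-gated U-Net** baseline (4 pooling stages, 16×
  down-sampling, additive attention gates on the skip connections);
* the composite objective
  `L = Tversky(final) + Σ_levels (wIoU + wBCE)` where the Tversky index
  TI = TP/(TP + α·FP + β·FN) generalises Dice with an asymmetric
  false-positive/false-negative trade-off, and the boundary-weighted
  structure terms supervise each decoder level's partial heatmap;
* **2D / 2.5D / 3D training regimes**: class-balanced slice batches,
  15-slice channel stacks (target ± 7 neighbours), and 96³ patch training
  with Gaussian-blended sliding-window inference;
* **object-level metrics**: Dice/Jaccard plus per-node scoring under the
  80%-coverage rule (a node spanning 3 slices with per-slice coverage
  0.9/0.85/0.6 scores 2/3);
* a **phantom generator** reproducing the statistical regime: few small
  bright ellipsoids per volume, vessel-like tubular confounders of similar
  intensity, > 70% node-free slices.

Because no deep-learning framework is assumed, the networks run on a small
reverse-mode autodiff engine over numpy included in the package
(`nodeseg.nn`), with finite-difference-verified gradients.

## Worked example

```python
import numpy as np
from nodeseg.phantom import easy_config, generate_cohort
from nodeseg.data import split_patients
from nodeseg.engine import TrainConfig, train, predict_2d
from nodeseg.metrics import evaluate_volume

samples, manifest, stats = generate_cohort(51, easy_config(), seed=1)
print(f"node-free slices: {100 * stats['empty_slice_fraction']:.1f}%")

split = split_patients([s.patient_id for s in samples],
                       fractions=(40, 10, 1), seed=1)
cfg = TrainConfig(mode="2d", learning_rate=5e-3, epochs=30,
                  steps_per_epoch=8, target_val_dice=0.80, seed=1)
ckpt, history = train({"arch": "snet", "ndim": 2, "base": 8, "seed": 1},
                      cfg, samples, split)
print(f"best validation Dice: {ckpt.best_val_dice:.3f} "
      f"after {len(history)} epochs")

vol = next(v for v in samples          # the held-out test phantom
           if split.assignment[v.patient_id] == "test")
report = evaluate_volume(predict_2d(ckpt, vol), vol.mask)
print(f"accurate slice-objects: {report.accurate_predictions}, "
      f"misses: {report.misses}")
```

Output from this exact script (single CPU, ~1 minute of training):

```
node-free slices: 45.8%
best validation Dice: 0.833 after 6 epochs
accurate slice-objects: 3, misses: 10
```

The validation Dice is pooled over all validation voxels; 0.80+ on the easy
high-contrast cohort indicates the optimisation pipeline works, not clinical
performance.  The object report illustrates how much stricter the
80%-coverage rule is than pixel Dice: training was stopped the moment Dice
crossed 0.80, and at that point only 3 of the 13 node-slices on the held-out
phantom are covered at ≥ 80% — longer training drives this up.

A `nodeseg` console command exposes the same pipeline from the shell
(`nodeseg generate | split | train | finetune | predict | evaluate`); every
subcommand takes `--help`.

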
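"""Composite segmentation objective.

The final prediction is scored with the Tversky loss, 1 - TP/(TP + a*FP + b*FN)
on soft (probabilistic) counts, which generalises the Dice loss with an
asymmetric trade-off between false positives and false negatives; with
a = b = 0.5 it reduces exactly to the soft Dice loss.  The default a = 0.3,
b = 0.7 weights missed foreground more heavily than spurious foreground,
the appropriate asymmetry when the object of interest is a handful of
pixels that must not be missed.

Intermediate decoder heatmaps are scored with a boundary-weighted IoU plus
boundary-weighted BCE ("structure loss"): each pixel carries weight
w = 1 + lam * |meanpool_k(g) - g|, which vanishes far from the mask boundary
and grows where a k-sized neighbourhood straddles it, concentrating the
gradient on small-object boundaries.

Total objective: tversky(final) + sum over decoder heatmaps of (wIoU + wBCE).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .nn.tensor import Tensor, astensor, softplus

__all__ = ["LossConfig", "LossTerms", "tversky_loss", "weighted_bce",
           "weighted_iou", "total_loss", "boundary_weights"]


@dataclasses.dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.3          # FP weight in the Tversky index
    beta: float = 0.7           # FN weight
    smooth: float = 1e-6
    lam: float = 5.0            # boundary-weight amplitude
    pool_k: int = 31            # boundary-weight pooling window (use 15 for 96^3 patches)
    use_structure: bool = True


@dataclasses.dataclass
class LossTerms:
    """All loss components; ``total`` keeps the autodiff graph for backward."""

    TP: float
    FP: float
    FN: float
    alpha: float
    beta: float
    TI: float
    tversky: float
    iou_w: list
    bce_w: list
    total: Tensor

    @property
    def total_value(self) -> float:
        return float(self.total.data)


def _soft_counts(prob, gt):
    p, g = astensor(prob), astensor(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = (p * g).sum()
    fp = (p * (1.0 - g)).sum()
    fn = ((1.0 - p) * g).sum()
    return tp, fp, fn


def tversky_loss(prob, gt, alpha: float = 0.3, beta: float = 0.7,
                 smooth: float = 1e-6):
    """1 - (TP + s) / (TP + a*FP + b*FN + s) on soft pixel counts.

    Returns a Tensor (scalar); differentiable in ``prob``.  The smoothing
    constant makes the loss 0 on all-empty slices with all-zero predictions,
    the dominant case in this data regime.
    """
    tp, fp, fn = _soft_counts(prob, gt)
    ti = (tp + smooth) / (tp + alpha * fp + beta * fn + smooth)
    return 1.0 - ti


def boundary_weights(gt: np.ndarray, lam: float = 5.0, k: int = 31) -> np.ndarray:
    """Pixel weight map 1 + lam*|meanpool_k(g) - g| over the trailing spatial axes."""
    g = np.asarray(gt, dtype=np.float64)
    # trailing axes are spatial: arrays of rank <= 3 are purely spatial,
    # rank >= 4 carries (batch, channel) in front
    nd = g.ndim if g.ndim <= 3 else g.ndim - 2
    if k > min(g.shape[-nd:]):
        raise ValueError(f"pooling window {k} larger than spatial extent {g.shape[-nd:]}")
    size = (1,) * (g.ndim - nd) + (k,) * nd
    pooled = ndimage.uniform_filter(g, size=size, mode="constant", cval=0.0)
    return 1.0 + lam * np.abs(pooled - g)


def weighted_bce(logits, gt, lam: float = 5.0, k: int = 31):
    """Boundary-weighted binary cross-entropy from pre-sigmoid logits."""
    x, g = astensor(logits), astensor(gt)
    if x.shape != g.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {g.shape}")
    w = boundary_weights(g.data, lam=lam, k=k)
    bce = softplus(x) - x * g          # = -[g*log(s) + (1-g)*log(1-s)], s=sigmoid(x)
    return (astensor(w) * bce).sum() / float(w.sum())


def weighted_iou(prob, gt, lam: float = 5.0, k: int = 31):
    """Boundary-weighted soft IoU loss: 1 - (sum w*p*g + 1)/(sum w*(p+g-p*g) + 1)."""
    p, g = astensor(prob), astensor(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    w = astensor(boundary_weights(g.data, lam=lam, k=k))
    inter = (w * p * g).sum()
    union = (w * (p + g - p * g)).sum()
    return 1.0 - (inter + 1.0) / (union + 1.0)


def total_loss(outputs, gt_mask, config: LossConfig = LossConfig()) -> LossTerms:
    """Tversky on the final probability plus structure loss on every heatmap.

    ``outputs`` is a SegOutputs (or anything with ``final_prob`` and
    ``partial_heatmaps``, the latter pre-sigmoid logits already upsampled to
    ground-truth resolution).
    """
    if getattr(outputs, "final_prob", None) is None:
        raise ValueError("outputs.final_prob is required")
    g = astensor(np.asarray(gt_mask, dtype=np.float32))
    p = astensor(outputs.final_prob)
    tp, fp, fn = _soft_counts(p, g)
    ti = (tp + config.smooth) / (tp + config.alpha * fp + config.beta * fn + config.smooth)
    tv = 1.0 - ti
    total = tv
    iou_terms, bce_terms = [], []
    heatmaps = outputs.partial_heatmaps if config.use_structure else []
    for hm in heatmaps:
        hm = astensor(hm)
        li = weighted_iou(hm.sigmoid(), g, lam=config.lam, k=config.pool_k)
        lb = weighted_bce(hm, g, lam=config.lam, k=config.pool_k)
        iou_terms.append(float(li.data))
        bce_terms.append(float(lb.data))
        total = total + li + lb
    return LossTerms(TP=float(tp.data), FP=float(fp.data), FN=float(fn.data),
                     alpha=config.alpha, beta=config.beta, TI=float(ti.data),
                     tversky=float(tv.data), iou_w=iou_terms, bce_w=bce_terms,
                     total=total)
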
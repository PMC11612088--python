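"""Training loops and inference for the 2D / 2.5D / 3D regimes.

Training follows the small-object recipe throughout: Adam with decoupled
weight decay, class-balanced batches for slice-based modes (equal numbers of
node-bearing and node-free slices per batch), one positive plus one negative
96^3 patch per volume per epoch for the 3D mode, the composite
Tversky + structure objective, model selection on validation Dice, and
fully seeded determinism.  Default learning rates are 5e-5 for 2D/2.5D and
1e-4 for 3D; default batch sizes 16 (2D) and 8 (2.5D/3D).

Inference is slice-wise reassembly for 2D/2.5D and Gaussian-blended
sliding-window tiling (window 96^3) for 3D.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as dio
from .losses import LossConfig, total_loss
from .networks import build_model
from .nn import AdamW, astensor, Tensor
from .nn.tensor import softplus
from .phantom import VolumeSample

__all__ = ["TrainConfig", "Checkpoint", "train", "finetune_aux", "predict_2d",
           "sliding_window_predict", "save_checkpoint", "load_checkpoint",
           "predict_volume"]

_MODE_LR = {"2d": 5e-5, "2.5d": 5e-5, "3d": 1e-4}
_MODE_BATCH = {"2d": 16, "2.5d": 8, "3d": 8}


@dataclasses.dataclass
class TrainConfig:
    """Run configuration; unset lr/batch_size resolve to the mode defaults."""

    mode: str = "2d"
    learning_rate: float | None = None
    batch_size: int | None = None
    epochs: int = 100
    steps_per_epoch: int | None = None      # None: full balanced epoch
    weight_decay: float = 1e-5
    patience: int = 15                      # early stopping on validation Dice
    target_val_dice: float | None = None    # optional convergence stop
    loss: LossConfig = dataclasses.field(default_factory=LossConfig)
    augment: dio.AugmentParams | None = None
    context: int = 7                        # 2.5D: slices either side of target
    patch_size: int = 96
    window: tuple = (-100.0, 300.0)
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODE_LR:
            raise ValueError(f"mode must be one of {sorted(_MODE_LR)}, got {self.mode!r}")
        if self.learning_rate is None:
            self.learning_rate = _MODE_LR[self.mode]
        if self.batch_size is None:
            self.batch_size = _MODE_BATCH[self.mode]
        if self.mode == "3d" and self.loss.pool_k == 31:
            # boundary-weight window shrinks with the 96^3 patch geometry
            self.loss = dataclasses.replace(self.loss, pool_k=15)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["loss"] = dataclasses.asdict(self.loss)
        d["augment"] = dataclasses.asdict(self.augment) if self.augment else None
        return d


@dataclasses.dataclass
class Checkpoint:
    model_config: dict
    train_config: dict
    state: dict
    best_val_dice: float = float("nan")

    def build(self):
        model = build_model(self.model_config)
        model.load_state_dict(self.state, strict=False)
        return model


def save_checkpoint(ckpt: Checkpoint, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"model_config": ckpt.model_config,
                       "train_config": ckpt.train_config,
                       "best_val_dice": ckpt.best_val_dice})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{k: v for k, v in ckpt.state.items()})


def load_checkpoint(path) -> Checkpoint:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return Checkpoint(model_config=meta["model_config"],
                      train_config=meta["train_config"], state=state,
                      best_val_dice=meta.get("best_val_dice", float("nan")))


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _partition_volumes(volumes, split):
    if split is None:
        return list(volumes), []
    by_id = {v.patient_id: v for v in volumes}
    train = [by_id[p] for p in split.ids("train") if p in by_id]
    val = [by_id[p] for p in split.ids("val") if p in by_id]
    return train, val


def _normalized(volume: VolumeSample, window) -> VolumeSample:
    return VolumeSample(image=dio.normalize_intensity(volume.image, window),
                        mask=volume.mask, spacing=volume.spacing,
                        patient_id=volume.patient_id)


def _slice_dataset(volumes, cfg: TrainConfig):
    """Per-slice inputs for 2D ((1,H,W)) or 2.5D ((2c+1,H,W)) training."""
    xs, ys, flags = [], [], []
    for v in volumes:
        for z in range(v.image.shape[0]):
            if cfg.mode == "2d":
                xs.append(v.image[z][None])
            else:
                xs.append(dio.make_stack_2p5d(v, z, context=cfg.context).image_stack)
            ys.append(v.mask[z][None])
            flags.append(bool(v.mask[z].any()))
    return xs, ys, np.asarray(flags)


def _global_dice(pred_fg: float, gt_fg: float, inter: float) -> float:
    denom = pred_fg + gt_fg
    return 1.0 if denom == 0 else 2.0 * inter / denom


def _validation_dice(model, val_volumes, cfg: TrainConfig) -> float:
    """Foreground Dice pooled over all validation volumes (already normalised)."""
    inter = pred_fg = gt_fg = 0.0
    for v in val_volumes:
        if cfg.mode in ("2d", "2.5d"):
            prob = _predict_slices(model, v, cfg.mode, cfg.context)
        else:
            prob = _sliding_window(model, v.image, window_size=cfg.patch_size)
        pred = prob >= cfg.threshold
        gt = v.mask.astype(bool)
        inter += np.logical_and(pred, gt).sum()
        pred_fg += pred.sum()
        gt_fg += gt.sum()
    return _global_dice(pred_fg, gt_fg, inter)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(model_config: dict, train_config: TrainConfig, volumes,
          split=None):
    """Train a model; returns (Checkpoint, history DataFrame).

    ``volumes`` is a list of VolumeSample; ``split`` (a SplitManifest)
    selects the train/val partitions by patient id.  The checkpoint holds
    the weights of the best validation-Dice epoch (or the final weights if
    no validation volumes are available).
    """
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    train_vols, val_vols = _partition_volumes(volumes, split)
    if not train_vols:
        raise ValueError("empty training partition")
    train_vols = [_normalized(v, cfg.window) for v in train_vols]
    val_vols = [_normalized(v, cfg.window) for v in val_vols]

    model = build_model(model_config)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)

    if cfg.mode in ("2d", "2.5d"):
        xs, ys, flags = _slice_dataset(train_vols, cfg)

    best_dice, best_state, best_epoch = -np.inf, None, -1
    rows = []
    for epoch in range(cfg.epochs):
        t0 = time.time()
        model.train()
        epoch_seed = int(rng.integers(2 ** 31))
        losses, tverskys = [], []
        if cfg.mode in ("2d", "2.5d"):
            batches = dio.balanced_batch_indices(flags, cfg.batch_size,
                                                 seed=epoch_seed)
            if cfg.steps_per_epoch is not None:
                batches = batches[:cfg.steps_per_epoch]
            batch_arrays = (( [xs[i] for i in b], [ys[i] for i in b]) for b in batches)
        else:
            batch_arrays = _patch_batches(train_vols, cfg, epoch_seed)
        step_rng = np.random.default_rng(epoch_seed + 1)
        for bx, by in batch_arrays:
            if cfg.augment is not None:
                aug_x, aug_y = [], []
                for img, msk in zip(bx, by):
                    s = int(step_rng.integers(2 ** 31))
                    if cfg.mode == "3d":
                        ai, am = dio.augment_3d(img[0], msk[0], cfg.augment, seed=s)
                        aug_x.append(ai[None])
                    else:
                        ai, am = dio.augment_2d(img, msk[0], cfg.augment, seed=s)
                        aug_x.append(ai)
                    aug_y.append(am[None])
                bx, by = aug_x, aug_y
            x = np.stack(bx).astype(np.float32)
            y = np.stack(by).astype(np.float32)
            out = model(x)
            terms = total_loss(out, y, cfg.loss)
            if not np.isfinite(terms.total_value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {terms.total_value}")
            terms.total.backward()
            opt.step()
            opt.zero_grad()
            losses.append(terms.total_value)
            tverskys.append(terms.tversky)
        model.eval()
        val_dice = _validation_dice(model, val_vols, cfg) if val_vols else float("nan")
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "tversky": float(np.mean(tverskys)),
                     "val_dice": val_dice, "seed": cfg.seed,
                     "seconds": time.time() - t0})
        if not val_vols or val_dice > best_dice:
            best_dice = val_dice if val_vols else float("nan")
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            best_epoch = epoch
        if cfg.target_val_dice is not None and val_dice >= cfg.target_val_dice:
            break
        if val_vols and epoch - best_epoch >= cfg.patience:
            break
    ckpt = Checkpoint(model_config=dict(model_config),
                      train_config=cfg.to_dict(), state=best_state,
                      best_val_dice=float(best_dice))
    return ckpt, pd.DataFrame(rows)


def _patch_batches(train_vols, cfg: TrainConfig, epoch_seed: int):
    """3D regime: 1 positive + 1 negative patch per volume per epoch."""
    rng = np.random.default_rng(epoch_seed)
    patches = []
    for v in train_vols:
        if v.mask.any():
            ps = dio.sample_patches_3d(v, patch_size=cfg.patch_size,
                                       n_positive=1, n_negative=1,
                                       seed=int(rng.integers(2 ** 31)))
        else:
            ps = dio.sample_patches_3d(v, patch_size=cfg.patch_size,
                                       n_positive=0, n_negative=2,
                                       seed=int(rng.integers(2 ** 31)))
        patches.extend(ps)
    order = rng.permutation(len(patches))
    if cfg.steps_per_epoch is not None:
        order = order[:cfg.steps_per_epoch * cfg.batch_size]
    for start in range(0, len(order), cfg.batch_size):
        chunk = [patches[i] for i in order[start:start + cfg.batch_size]]
        yield ([p.image[None] for p in chunk], [p.mask[None] for p in chunk])


# ---------------------------------------------------------------------------
# auxiliary-task finetuning
# ---------------------------------------------------------------------------

def _gaussian_center_heatmap(mask: np.ndarray, downsample: int = 4,
                             sigma_px: float = 3.0) -> np.ndarray:
    """Node-center heatmap target at 1/downsample resolution (sigma in full-res px)."""
    from scipy import ndimage
    h, w = mask.shape
    hh, ww = h // downsample, w // downsample
    target = np.zeros((hh, ww), dtype=np.float32)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return target
    yy, xx = np.mgrid[0:hh, 0:ww]
    s = sigma_px / downsample
    for cy, cx in ndimage.center_of_mass(mask, labels, range(1, n + 1)):
        target = np.maximum(target, np.exp(
            -((yy - cy / downsample) ** 2 + (xx - cx / downsample) ** 2) / (2 * s * s)
        ).astype(np.float32))
    return target


def finetune_aux(checkpoint: Checkpoint, task: str, train_config: TrainConfig,
                 volumes, split=None, lr_scale: float = 0.5):
    """Finetune a trained 2D/2.5D model jointly with an auxiliary head.

    ``task='classification'`` adds a slice-level node-presence logit
    (balanced BCE); ``task='localization'`` adds a low-resolution Gaussian
    center-heatmap regression (MSE).  Returns (Checkpoint, history).
    """
    if task not in ("classification", "localization"):
        raise ValueError(f"unknown auxiliary task {task!r}")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    train_vols, val_vols = _partition_volumes(volumes, split)
    train_vols = [_normalized(v, cfg.window) for v in train_vols]
    val_vols = [_normalized(v, cfg.window) for v in val_vols]

    model_config = dict(checkpoint.model_config, with_heads=True)
    model = build_model(model_config)
    model.load_state_dict(checkpoint.state, strict=False)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate * lr_scale,
                weight_decay=cfg.weight_decay)

    xs, ys, flags = _slice_dataset(train_vols, cfg)
    rows = []
    for epoch in range(cfg.epochs):
        model.train()
        epoch_seed = int(rng.integers(2 ** 31))
        batches = dio.balanced_batch_indices(flags, cfg.batch_size, seed=epoch_seed)
        if cfg.steps_per_epoch is not None:
            batches = batches[:cfg.steps_per_epoch]
        losses, head_losses = [], []
        for b in batches:
            x = np.stack([xs[i] for i in b]).astype(np.float32)
            y = np.stack([ys[i] for i in b]).astype(np.float32)
            out = model(x, with_heads=True)
            terms = total_loss(out, y, cfg.loss)
            if task == "classification":
                labels = astensor(flags[b].astype(np.float32).reshape(-1, 1))
                logits = out.class_logit
                head_loss = (softplus(logits) - logits * labels).mean()
            else:
                targets = np.stack([
                    _gaussian_center_heatmap(ys[i][0].astype(np.uint8))[None]
                    for i in b]).astype(np.float32)
                diff = out.loc_heatmap.sigmoid() - astensor(targets)
                head_loss = (diff * diff).mean()
            loss = terms.total + head_loss
            loss.backward()
            opt.step()
            opt.zero_grad()
            losses.append(float(loss.data))
            head_losses.append(float(head_loss.data))
        model.eval()
        val_dice = _validation_dice(model, val_vols, cfg) if val_vols else float("nan")
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "head_loss": float(np.mean(head_losses)),
                     "val_dice": val_dice, "seed": cfg.seed})
    ckpt = Checkpoint(model_config=model_config, train_config=cfg.to_dict(),
                      state=model.state_dict(),
                      best_val_dice=rows[-1]["val_dice"] if rows else float("nan"))
    return ckpt, pd.DataFrame(rows)


def classify_slices(model, volume: VolumeSample, window=(-100.0, 300.0),
                    mode: str = "2d", context: int = 7) -> np.ndarray:
    """Slice-level node-presence probabilities from the classification head."""
    v = _normalized(volume, window)
    model.eval()
    probs = []
    for z in range(v.image.shape[0]):
        x = v.image[z][None, None] if mode == "2d" else \
            dio.make_stack_2p5d(v, z, context=context).image_stack[None]
        out = model(x.astype(np.float32), with_heads=True)
        probs.append(out.class_logit.sigmoid().data.item())
    return np.asarray(probs)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _predict_slices(model, volume: VolumeSample, mode: str, context: int,
                    chunk: int = 8) -> np.ndarray:
    depth = volume.image.shape[0]
    if mode == "2d":
        stack = volume.image[:, None]
    else:
        stack = np.stack([dio.make_stack_2p5d(volume, z, context=context).image_stack
                          for z in range(depth)])
    probs = np.empty_like(volume.image, dtype=np.float32)
    for start in range(0, depth, chunk):
        out = model(stack[start:start + chunk].astype(np.float32))
        probs[start:start + chunk] = out.final_prob.data[:, 0]
    return probs


def predict_2d(checkpoint: Checkpoint, volume: VolumeSample) -> np.ndarray:
    """Slice-wise probability volume from a 2D or 2.5D checkpoint."""
    cfg = checkpoint.train_config
    mode = cfg.get("mode", "2d")
    if mode not in ("2d", "2.5d"):
        raise ValueError(f"predict_2d needs a 2d/2.5d checkpoint, got mode {mode!r}")
    model = checkpoint.build()
    model.eval()
    v = _normalized(volume, tuple(cfg.get("window", (-100.0, 300.0))))
    return _predict_slices(model, v, mode, int(cfg.get("context", 7)))


def _gaussian_importance(window_size: int, nd: int) -> np.ndarray:
    ax = np.arange(window_size, dtype=np.float64)
    c = (window_size - 1) / 2.0
    g1 = np.exp(-((ax - c) ** 2) / (2 * (window_size / 8.0) ** 2))
    out = g1
    for _ in range(nd - 1):
        out = np.multiply.outer(out, g1)
    return np.maximum(out, 1e-6)


def _tile_starts(extent: int, window: int, overlap: float):
    step = max(1, int(round(window * (1 - overlap))))
    starts = list(range(0, max(extent - window, 0) + 1, step))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return sorted(set(starts))


def _sliding_window(model, image: np.ndarray, window_size: int = 96,
                    overlap: float = 0.5) -> np.ndarray:
    nd = image.ndim
    pads = [(0, max(0, window_size - s)) for s in image.shape]
    padded = np.pad(image, pads, mode="edge") if any(p[1] for p in pads) else image
    acc = np.zeros(padded.shape, dtype=np.float64)
    wacc = np.zeros(padded.shape, dtype=np.float64)
    wmap = _gaussian_importance(window_size, nd)
    starts = [_tile_starts(s, window_size, overlap) for s in padded.shape]
    import itertools
    for origin in itertools.product(*starts):
        sl = tuple(slice(o, o + window_size) for o in origin)
        out = model(padded[sl][None, None].astype(np.float32))
        acc[sl] += out.final_prob.data[0, 0].astype(np.float64) * wmap
        wacc[sl] += wmap
    prob = (acc / wacc).astype(np.float32)
    crop = tuple(slice(0, s) for s in image.shape)
    return prob[crop]


def sliding_window_predict(checkpoint: Checkpoint, volume: VolumeSample,
                           window_size: int = 96, overlap: float = 0.5) -> np.ndarray:
    """Tiled 3D inference with Gaussian-blended overlaps.

    Volumes smaller than the window are edge-padded, predicted and cropped.
    A volume that fits in a single tile reduces exactly to the direct
    forward pass.
    """
    cfg = checkpoint.train_config
    if cfg.get("mode") != "3d":
        raise ValueError("sliding_window_predict needs a 3d checkpoint")
    model = checkpoint.build()
    model.eval()
    v = _normalized(volume, tuple(cfg.get("window", (-100.0, 300.0))))
    return _sliding_window(model, v.image, window_size=window_size, overlap=overlap)


def predict_volume(checkpoint: Checkpoint, volume: VolumeSample) -> np.ndarray:
    """Mode-appropriate probability volume."""
    if checkpoint.train_config.get("mode") == "3d":
        return sliding_window_predict(checkpoint, volume)
    return predict_2d(checkpoint, volume)
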
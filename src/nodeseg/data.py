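"""Dataset plumbing: patient-level splits, 2D/2.5D/3D sample construction,
class-balanced batch sampling, augmentation and intensity normalisation.

Conventions: 0-based voxel indices, axial slices along the first array axis,
masks stored as unsigned bytes.  All randomness is driven by explicit seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import VolumeSample

__all__ = ["SplitManifest", "SliceSample", "Stack2p5D", "Patch3D", "AugmentParams",
           "split_patients", "make_stack_2p5d", "sample_patches_3d",
           "balanced_batch_indices", "augment_2d", "augment_3d",
           "normalize_intensity"]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SplitManifest:
    """Patient -> partition assignment; partitions are disjoint and exhaustive."""

    assignment: dict            # patient_id -> "train" | "val" | "test"
    fractions: tuple
    seed: int

    def ids(self, partition: str) -> list:
        return [pid for pid, p in self.assignment.items() if p == partition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": list(self.assignment),
                             "partition": list(self.assignment.values())})


_PARTITIONS = ("train", "val", "test")


def split_patients(patient_ids, fractions=(160 / 221, 40 / 221, 21 / 221),
                   seed: int = 0) -> SplitManifest:
    """Patient-level split into train/val/test.

    ``fractions`` may be proportions (summing to 1) or integer counts summing
    to the number of patients.  Deterministic: ids are sorted, then shuffled
    with the given seed.
    """
    ids = sorted(str(p) for p in patient_ids)
    n = len(ids)
    if n < len(_PARTITIONS):
        raise ValueError(f"need at least {len(_PARTITIONS)} patients, got {n}")
    fr = tuple(fractions)
    if all(float(f).is_integer() for f in fr) and sum(fr) == n:
        counts = tuple(int(f) for f in fr)
    else:
        if not np.isclose(sum(fr), 1.0):
            raise ValueError("fractions must sum to 1 (or be counts summing to n)")
        counts = [int(np.floor(f * n)) for f in fr]
        for i in np.argsort([f * n - c for f, c in zip(fr, counts)])[::-1]:
            if sum(counts) == n:
                break
            counts[i] += 1
        # proportional rounding may starve a partition on tiny cohorts
        while min(counts) < 1:
            counts[int(np.argmax(counts))] -= 1
            counts[int(np.argmin(counts))] += 1
        counts = tuple(counts)
    if min(counts) < 1:
        raise ValueError(f"every partition needs at least one patient: {counts}")
    order = np.random.default_rng(seed).permutation(n)
    assignment, start = {}, 0
    for part, cnt in zip(_PARTITIONS, counts):
        for j in order[start:start + cnt]:
            assignment[ids[j]] = part
        start += cnt
    assignment = {pid: assignment[pid] for pid in ids}
    return SplitManifest(assignment=assignment, fractions=fr, seed=seed)


# ---------------------------------------------------------------------------
# sample containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SliceSample:
    image: np.ndarray
    mask: np.ndarray
    has_node: bool
    patient_id: str
    slice_index: int

    def __post_init__(self):
        if bool(self.mask.any()) != self.has_node:
            raise ValueError("has_node flag inconsistent with mask content")


@dataclasses.dataclass
class Stack2p5D:
    """Multi-slice context stack: target slice with symmetric neighbours as channels."""

    image_stack: np.ndarray     # (2*context+1, H, W)
    mask: np.ndarray            # (H, W), centre slice only
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        if self.image_stack.ndim != 3:
            raise ValueError("image_stack must be (channels, H, W)")
        if self.image_stack.shape[0] % 2 != 1:
            raise ValueError("channel count must be odd (centre slice + symmetric context)")


@dataclasses.dataclass
class Patch3D:
    image: np.ndarray
    mask: np.ndarray
    polarity: str               # "positive" | "negative"

    def __post_init__(self):
        fg = int(self.mask.sum())
        if self.polarity == "positive" and fg < 1:
            raise ValueError("positive patch without foreground")
        if self.polarity == "negative" and fg != 0:
            raise ValueError("negative patch with foreground")


def volume_slices(volume: VolumeSample) -> list:
    """All axial slices of a volume as SliceSample objects."""
    out = []
    for z in range(volume.image.shape[0]):
        m = volume.mask[z]
        out.append(SliceSample(image=volume.image[z], mask=m,
                               has_node=bool(m.any()),
                               patient_id=volume.patient_id, slice_index=z))
    return out


def make_stack_2p5d(volume: VolumeSample, slice_index: int, context: int = 7) -> Stack2p5D:
    """Build the (2*context+1)-channel stack centred on ``slice_index``.

    Out-of-range neighbours are filled by edge replication so the channel
    count is the same everywhere in the volume.
    """
    if context < 0:
        raise ValueError("context must be >= 0")
    depth = volume.image.shape[0]
    if not 0 <= slice_index < depth:
        raise IndexError(f"slice_index {slice_index} outside [0, {depth})")
    idx = np.clip(np.arange(slice_index - context, slice_index + context + 1), 0, depth - 1)
    return Stack2p5D(image_stack=volume.image[idx],
                     mask=volume.mask[slice_index],
                     patient_id=volume.patient_id, slice_index=slice_index)


def sample_patches_3d(volume: VolumeSample, patch_size: int = 96,
                      n_positive: int = 1, n_negative: int = 1,
                      seed: int = 0, jitter: int = 16,
                      max_retries: int = 500) -> list:
    """Crop fixed-size cubic patches of declared polarity from a volume.

    Positive patches are centred on a uniformly drawn foreground voxel,
    jittered within +/-``jitter`` voxels and clipped to bounds; negative
    patches are rejection-sampled until free of foreground.  Volumes smaller
    than the patch are edge-padded (image) / zero-padded (mask) first.
    """
    rng = np.random.default_rng(seed)
    img, msk = volume.image, volume.mask
    pads = [(0, max(0, patch_size - s)) for s in img.shape]
    if any(p[1] for p in pads):
        img = np.pad(img, pads, mode="edge")
        msk = np.pad(msk, pads, mode="constant")
    shape = img.shape
    fg = np.argwhere(msk > 0)
    if n_positive > 0 and len(fg) == 0:
        raise ValueError("volume has no foreground; cannot draw positive patches")

    def crop(start):
        sl = tuple(slice(s, s + patch_size) for s in start)
        return img[sl], msk[sl]

    patches = []
    for _ in range(n_positive):
        for _attempt in range(max_retries):
            v = fg[rng.integers(len(fg))]
            start = v - patch_size // 2 + rng.integers(-jitter, jitter + 1, size=3)
            start = np.clip(start, 0, np.array(shape) - patch_size)
            ci, cm = crop(start)
            if cm.any():
                patches.append(Patch3D(image=ci, mask=cm, polarity="positive"))
                break
        else:
            raise RuntimeError("failed to draw a positive patch")
    for _ in range(n_negative):
        for _attempt in range(max_retries):
            start = np.array([rng.integers(0, shape[i] - patch_size + 1) for i in range(3)])
            ci, cm = crop(start)
            if not cm.any():
                patches.append(Patch3D(image=ci, mask=cm, polarity="negative"))
                break
        else:
            raise RuntimeError("failed to draw a foreground-free patch")
    return patches


def balanced_batch_indices(has_node_flags, batch_size: int, seed: int = 0) -> list:
    """Index batches with exactly batch_size/2 positive and negative samples.

    One epoch covers the majority class once (full batches only); the
    minority class is resampled with replacement to match.
    """
    if batch_size % 2 != 0:
        raise ValueError("batch_size must be even for balanced batches")
    flags = np.asarray(has_node_flags, dtype=bool)
    pos = np.flatnonzero(flags)
    neg = np.flatnonzero(~flags)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need at least one positive and one negative sample")
    rng = np.random.default_rng(seed)
    half = batch_size // 2
    n_batches = max(1, max(len(pos), len(neg)) // half)
    need = n_batches * half

    def epoch_stream(idx):
        reps = int(np.ceil(need / len(idx)))
        stream = np.concatenate([rng.permutation(idx) for _ in range(reps)])
        return stream[:need]

    ps, ns = epoch_stream(pos), epoch_stream(neg)
    batches = []
    for b in range(n_batches):
        batch = np.concatenate([ps[b * half:(b + 1) * half], ns[b * half:(b + 1) * half]])
        batches.append(rng.permutation(batch))
    return batches


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AugmentParams:
    """Stochastic augmentation ranges for 2D/2.5D slices and 3D patches.

    2D: rotation in degrees within [-10, 10], vertical flip, multiplicative
    brightness/contrast, gamma.  3D: affine with per-axis rotation range
    (0, 0, pi/15) (radians, z-axis only), per-axis scale range 0.1, additive
    intensity shift 0.1.
    """

    rotation_deg: tuple = (-10.0, 10.0)
    vflip_prob: float = 0.5
    brightness_limit: float = 0.1
    contrast_limit: float = 0.1
    gamma_limit: tuple = (0.9, 1.1)
    rotate_range_3d: tuple = (0.0, 0.0, np.pi / 15)
    scale_range_3d: tuple = (0.1, 0.1, 0.1)
    intensity_offset_3d: float = 0.1

    def __post_init__(self):
        lo, hi = self.rotation_deg
        if lo < -10.0 - 1e-9 or hi > 10.0 + 1e-9 or hi < lo:
            raise ValueError("2D rotation interval must lie within [-10, +10] degrees")

    @classmethod
    def identity(cls):
        return cls(rotation_deg=(0.0, 0.0), vflip_prob=0.0, brightness_limit=0.0,
                   contrast_limit=0.0, gamma_limit=(1.0, 1.0),
                   rotate_range_3d=(0.0, 0.0, 0.0), scale_range_3d=(0.0, 0.0, 0.0),
                   intensity_offset_3d=0.0)


def _check_pair(image, mask):
    if image.shape[-2:] != mask.shape[-2:] and image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary")


def augment_2d(image: np.ndarray, mask: np.ndarray, params: AugmentParams,
               seed: int = 0):
    """Jointly augment a slice (or channel stack) and its binary mask.

    Geometric transforms hit image and mask identically (mask resampled with
    nearest neighbour, so it stays binary); photometric transforms hit the
    image only.  Gamma assumes intensities already normalised to [0, 1].
    """
    _check_pair(image, mask)
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float32).copy()
    msk = np.asarray(mask, dtype=np.uint8).copy()
    multichannel = img.ndim == 3

    angle = rng.uniform(*params.rotation_deg)
    if angle != 0.0:
        axes = (-2, -1)
        img = ndimage.rotate(img, angle, axes=axes, reshape=False, order=1,
                             mode="nearest")
        msk = ndimage.rotate(msk, angle, axes=axes, reshape=False, order=0,
                             mode="constant")
    if rng.uniform() < params.vflip_prob:
        img = img[..., ::-1, :].copy()
        msk = msk[..., ::-1, :].copy()
    if params.brightness_limit > 0 or params.contrast_limit > 0:
        b = rng.uniform(-params.brightness_limit, params.brightness_limit)
        c = 1.0 + rng.uniform(-params.contrast_limit, params.contrast_limit)
        img = img * c + b
    g_lo, g_hi = params.gamma_limit
    if (g_lo, g_hi) != (1.0, 1.0):
        gamma = rng.uniform(g_lo, g_hi)
        img = np.clip(img, 0.0, 1.0) ** gamma
    del multichannel
    return img, msk


def augment_3d(image: np.ndarray, mask: np.ndarray, params: AugmentParams,
               seed: int = 0):
    """Random affine (z-rotation + per-axis scaling) and intensity shift in 3D."""
    _check_pair(image, mask)
    rng = np.random.default_rng(seed)
    img = np.asarray(image, dtype=np.float32)
    msk = np.asarray(mask, dtype=np.uint8)

    angles = [rng.uniform(-r, r) if r > 0 else 0.0 for r in params.rotate_range_3d]
    scales = [1.0 + (rng.uniform(-s, s) if s > 0 else 0.0) for s in params.scale_range_3d]
    theta = angles[2]                      # rotation about the z (slice) axis
    rot = np.array([[1, 0, 0],
                    [0, np.cos(theta), -np.sin(theta)],
                    [0, np.sin(theta), np.cos(theta)]])
    mat = rot @ np.diag(scales)
    if not np.allclose(mat, np.eye(3)):
        center = (np.array(img.shape) - 1) / 2.0
        # affine_transform maps output coords through `matrix` into the input
        inv = np.linalg.inv(mat)
        offset = center - inv @ center
        img = ndimage.affine_transform(img, inv, offset=offset, order=1,
                                       mode="nearest").astype(np.float32)
        msk = ndimage.affine_transform(msk, inv, offset=offset, order=0,
                                       mode="constant")
    if params.intensity_offset_3d > 0:
        img = img + rng.uniform(-params.intensity_offset_3d, params.intensity_offset_3d)
    return img, msk


def normalize_intensity(image: np.ndarray, window=(-100.0, 300.0)) -> np.ndarray:
    """Clip to an HU window and scale linearly to [0, 1]."""
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"degenerate window {window}")
    img = np.clip(np.asarray(image, dtype=np.float32), lo, hi)
    return (img - lo) / (hi - lo)
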
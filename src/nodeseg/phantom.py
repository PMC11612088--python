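"""Synthetic CT-like phantom cohorts for small-lymph-node segmentation.

Real cervical-node CT cohorts are dominated by three statistical features
that make the segmentation task hard: the foreground objects are small
(5–10 mm long axis) bright ellipsoids occupying well under 1% of voxels,
most axial slices contain no node at all, and tubular vessels of similar
contrast run through the volume and mimic nodes on any single slice.  The
generator reproduces exactly these features on top of a noisy soft-tissue
background, so every downstream stage (sampling, training, object-level
scoring) can be exercised without any clinical data.

Nodes are rendered as randomly rotated triaxial ellipsoids; a Gaussian blur
applied to the object intensity field gives sub-voxel partial-volume edges.
Vessels are random-walk tubes spanning the volume in z, drawn in the image
with the same contrast distribution as the nodes but never labelled in the
mask — they are deliberate false-positive bait.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomConfig", "VolumeSample", "NodePlacementError",
           "generate_phantom", "generate_cohort", "easy_config",
           "save_volume", "load_volume"]


class NodePlacementError(RuntimeError):
    """Raised when a node cannot be placed without overlap within the retry budget."""


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one phantom cohort, HU-like intensity units.

    Defaults encode the target data regime: 1–3 nodes of 5–10 mm long axis
    per volume and enough node-free axial slices that, over a cohort, more
    than 70% of slices carry no foreground.
    """

    volume_shape: tuple = (48, 96, 96)          # (z, y, x) voxels
    spacing: tuple = (1.0, 1.0, 1.0)            # mm per axis
    n_nodes_range: tuple = (1, 3)               # inclusive interval
    node_long_axis_mm: tuple = (5.0, 10.0)
    node_aspect_range: tuple = (0.5, 0.8)       # short/long semi-axis ratio
    n_vessels_range: tuple = (1, 3)
    vessel_radius_mm: tuple = (1.0, 2.5)
    background_mean: float = 60.0
    background_sd: float = 15.0
    node_contrast: float = 40.0
    vessel_contrast: float | None = None        # None -> same as node_contrast
    edge_sigma_vox: float = 0.7                 # partial-volume blur of objects
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        for name in ("n_nodes_range", "node_long_axis_mm", "node_aspect_range",
                     "n_vessels_range", "vessel_radius_mm"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.node_long_axis_mm[0] < 2 * max(self.spacing):
            raise ValueError("node long axis must be at least twice the coarsest spacing")

    @property
    def vessel_contrast_value(self) -> float:
        return self.node_contrast if self.vessel_contrast is None else self.vessel_contrast


@dataclasses.dataclass
class VolumeSample:
    """One patient's image volume, binary node mask and voxel spacing."""

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple
    patient_id: str

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        if self.mask.mean() >= 0.01:
            raise ValueError("foreground exceeds 1% of voxels; not a small-object volume")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm, rotation) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the rotated ellipsoid."""
    half = max(semi_axes_mm)
    lo = [max(0, int(np.floor((center_mm[i] - half) / spacing[i])) - 1) for i in range(3)]
    hi = [min(shape[i], int(np.ceil((center_mm[i] + half) / spacing[i])) + 2) for i in range(3)]
    grids = np.meshgrid(*[np.arange(lo[i], hi[i]) * spacing[i] - center_mm[i]
                          for i in range(3)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids])         # (3, n) in mm, centred
    local = rotation.T @ pts
    q = ((local / np.asarray(semi_axes_mm)[:, None]) ** 2).sum(axis=0)
    out = np.zeros(shape, dtype=bool)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (q <= 1.0).reshape(grids[0].shape)
    return out


def generate_phantom(config: PhantomConfig, seed: int | None = None,
                     patient_id: str = "P0000", max_retries: int = 200):
    """Render one phantom volume.

    Returns ``(VolumeSample, node_metadata)`` where the metadata is a list of
    dicts (center_mm, semi_axes_mm, rotation) for every placed node.
    Deterministic for a fixed (config, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = tuple(config.volume_shape)
    spacing = tuple(config.spacing)
    extent_mm = np.array([shape[i] * spacing[i] for i in range(3)])

    image = rng.normal(config.background_mean, config.background_sd,
                       size=shape).astype(np.float32)
    objects = np.zeros(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint8)

    # vessels first: tubes spanning z, random-walk centreline, never labelled
    n_vessels = int(rng.integers(config.n_vessels_range[0], config.n_vessels_range[1] + 1))
    yy, xx = np.meshgrid(np.arange(shape[1]) * spacing[1],
                         np.arange(shape[2]) * spacing[2], indexing="ij")
    for _ in range(n_vessels):
        r = rng.uniform(*config.vessel_radius_mm)
        cy = rng.uniform(0.15, 0.85) * extent_mm[1]
        cx = rng.uniform(0.15, 0.85) * extent_mm[2]
        for z in range(shape[0]):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
            objects[z][disk] = config.vessel_contrast_value
            cy += rng.normal(0, 0.6 * spacing[0])
            cx += rng.normal(0, 0.6 * spacing[0])
            cy = float(np.clip(cy, 0, extent_mm[1]))
            cx = float(np.clip(cx, 0, extent_mm[2]))
    vessel_voxels = objects > 0

    n_nodes = int(rng.integers(config.n_nodes_range[0], config.n_nodes_range[1] + 1))
    occupied = ndimage.binary_dilation(vessel_voxels, iterations=2)
    metadata = []
    for _ in range(n_nodes):
        placed = False
        for _attempt in range(max_retries):
            long_axis = rng.uniform(*config.node_long_axis_mm)
            a = long_axis / 2.0
            b = a * rng.uniform(*config.node_aspect_range)
            c = a * rng.uniform(*config.node_aspect_range)
            rot = _random_rotation(rng)
            # keep the node inside the volume; on axes thinner than the node
            # the centre collapses to the middle and the ellipsoid truncates
            margin = a + max(spacing)
            lo_b = np.minimum(margin, extent_mm / 2)
            hi_b = np.maximum(extent_mm - margin, lo_b)
            center = rng.uniform(lo_b, hi_b)
            ell = _ellipsoid_mask(shape, spacing, center, (a, b, c), rot)
            if not ell.any() or (ell & occupied).any():
                continue
            mask[ell] = 1
            objects[ell] = config.node_contrast
            occupied |= ndimage.binary_dilation(ell, iterations=2)
            metadata.append({"center_mm": center, "semi_axes_mm": (a, b, c),
                             "rotation": rot})
            placed = True
            break
        if not placed:
            raise NodePlacementError(
                f"could not place node without overlap after {max_retries} retries")

    if config.edge_sigma_vox > 0:
        objects = ndimage.gaussian_filter(objects, config.edge_sigma_vox)
    image += objects
    sample = VolumeSample(image=image, mask=mask, spacing=spacing, patient_id=patient_id)
    return sample, metadata


def easy_config(seed: int = 0) -> PhantomConfig:
    """High-contrast small-volume cohort used for desk-scale learning studies.

    64x64 axial slices, 12 slices deep, nodes at +150 HU over background —
    easy enough that a correct implementation learns it in a few epochs on a
    single CPU.  Vessels are kept as structural confounders but at reduced
    contrast (+40): at equal contrast a slice-wise model cannot separate a
    vessel cross-section from a node at all, which is the *hard* regime the
    default config encodes, not a learnability check.
    """
    return PhantomConfig(volume_shape=(12, 64, 64), n_nodes_range=(1, 2),
                         n_vessels_range=(1, 2), node_contrast=150.0,
                         vessel_contrast=40.0, seed=seed)


def save_volume(sample: VolumeSample, image_path, mask_path):
    """Write image and mask as NIfTI with spacing in the header.

    First array axis is the axial (z) direction throughout this package.
    """
    import nibabel as nib

    affine = np.diag(list(sample.spacing) + [1.0])
    nib.save(nib.Nifti1Image(sample.image.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(sample.mask.astype(np.uint8), affine), str(mask_path))


def load_volume(image_path, mask_path, patient_id: str | None = None) -> VolumeSample:
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    pid = patient_id or Path(str(image_path)).stem.split(".")[0]
    return VolumeSample(image=np.asanyarray(img.dataobj, dtype=np.float32),
                        mask=np.asanyarray(msk.dataobj, dtype=np.uint8),
                        spacing=spacing, patient_id=pid)


def generate_cohort(n_patients: int, config: PhantomConfig, seed: int = 0,
                    out_dir=None, overwrite: bool = False):
    """Generate a cohort of phantoms with unique patient ids.

    Returns ``(samples, manifest, stats)``: the list of VolumeSample, a
    pandas manifest (patient_id, image_path, mask_path, n_nodes), and a dict
    with the cohort-level fraction of node-free axial slices.  When
    ``out_dir`` is given, image/mask pairs are written as .nii.gz and the
    manifest as manifest.csv.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
        out.mkdir(parents=True, exist_ok=True)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_patients)
    samples, rows = [], []
    empty_slices = total_slices = 0
    for i in range(n_patients):
        pid = f"P{i + 1:04d}"
        sample, meta = generate_phantom(config, seed=int(child_seeds[i]) % (2 ** 31),
                                        patient_id=pid)
        samples.append(sample)
        slice_has_fg = sample.mask.reshape(sample.mask.shape[0], -1).any(axis=1)
        empty_slices += int((~slice_has_fg).sum())
        total_slices += sample.mask.shape[0]
        img_path = mask_path = ""
        if out is not None:
            img_path = str(out / f"{pid}_image.nii.gz")
            mask_path = str(out / f"{pid}_mask.nii.gz")
            save_volume(sample, img_path, mask_path)
        rows.append({"patient_id": pid, "image_path": img_path,
                     "mask_path": mask_path, "n_nodes": len(meta)})
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    stats = {"empty_slice_fraction": empty_slices / total_slices,
             "n_slices": total_slices}
    return samples, manifest, stats
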
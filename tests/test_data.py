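"""Split disjointness, 2.5D stacking, patch polarity, balanced sampling and
augmentation alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodeseg.data import (AugmentParams, balanced_batch_indices, augment_2d,
                          augment_3d, make_stack_2p5d, normalize_intensity,
                          sample_patches_3d, split_patients)
from nodeseg.phantom import PhantomConfig, VolumeSample, generate_phantom


# ---------------------------------------------------------------------------
# patient-level splitting
# ---------------------------------------------------------------------------

def test_study_scale_split_counts():
    ids = [f"P{i:04d}" for i in range(1, 222)]
    sm = split_patients(ids, fractions=(160, 40, 21), seed=3)
    assert (len(sm.ids("train")), len(sm.ids("val")), len(sm.ids("test"))) == (160, 40, 21)


def test_three_patients_one_each():
    sm = split_patients(["a", "b", "c"], fractions=(1, 1, 1), seed=0)
    parts = [sm.assignment[p] for p in "abc"]
    assert sorted(parts) == ["test", "train", "val"]


@settings(deadline=None, max_examples=25)
@given(n=st.integers(5, 120), seed=st.integers(0, 10 ** 6))
def test_split_partitions_disjoint_and_exhaustive(n, seed):
    ids = [f"p{i}" for i in range(n)]
    sm = split_patients(ids, seed=seed)
    groups = [set(sm.ids(p)) for p in ("train", "val", "test")]
    assert groups[0] | groups[1] | groups[2] == set(ids)
    assert not (groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2])


def test_split_determinism_and_errors():
    ids = [f"p{i}" for i in range(10)]
    a = split_patients(ids, seed=5)
    b = split_patients(ids, seed=5)
    assert a.assignment == b.assignment
    with pytest.raises(ValueError):
        split_patients(["a", "b"], fractions=(1, 1, 1), seed=0)
    with pytest.raises(ValueError):
        split_patients(ids, fractions=(0.5, 0.2, 0.2), seed=0)


# ---------------------------------------------------------------------------
# 2.5D stacks
# ---------------------------------------------------------------------------

def _toy_volume(depth=100):
    img = np.broadcast_to(np.arange(depth, dtype=np.float32)[:, None, None],
                          (depth, 8, 8)).copy()
    mask = np.zeros_like(img, dtype=np.uint8)
    mask[50, 2:4, 2:4] = 1
    return VolumeSample(image=img, mask=mask, spacing=(1, 1, 1), patient_id="t")


def test_stack_center_and_neighbour_channels():
    v = _toy_volume()
    st15 = make_stack_2p5d(v, 50, context=7)
    assert st15.image_stack.shape[0] == 15
    assert np.array_equal(st15.image_stack[:, 0, 0], np.arange(43, 58))
    assert np.array_equal(st15.image_stack[7], v.image[50])  # centre channel
    assert np.array_equal(st15.mask, v.mask[50])


def test_stack_edge_replication_and_degenerate_context():
    v = _toy_volume()
    first = make_stack_2p5d(v, 0, context=7)
    assert np.array_equal(first.image_stack[:8, 0, 0],
                          np.zeros(8))            # 7 leading copies of slice 0
    assert np.array_equal(first.image_stack[8:, 0, 0], np.arange(1, 8))
    single = make_stack_2p5d(v, 42, context=0)
    assert single.image_stack.shape == (1, 8, 8)
    assert np.array_equal(single.image_stack[0], v.image[42])
    with pytest.raises(ValueError):
        make_stack_2p5d(v, 5, context=-1)
    with pytest.raises(IndexError):
        make_stack_2p5d(v, 100, context=7)


# ---------------------------------------------------------------------------
# 3D patch sampling
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def patch_volume():
    cfg = PhantomConfig(volume_shape=(48, 48, 48), n_nodes_range=(1, 1),
                        n_vessels_range=(1, 1))
    sample, _ = generate_phantom(cfg, seed=13)
    return sample


def test_patch_polarity_contract_over_many_seeds(patch_volume):
    for seed in range(100):
        pos, neg = sample_patches_3d(patch_volume, patch_size=32,
                                     n_positive=1, n_negative=1, seed=seed)
        assert pos.polarity == "positive" and pos.mask.sum() >= 1
        assert neg.polarity == "negative" and neg.mask.sum() == 0
        assert pos.image.shape == (32, 32, 32)


def test_patch_sampling_edge_cases(patch_volume):
    empty = VolumeSample(image=patch_volume.image,
                         mask=np.zeros_like(patch_volume.mask),
                         spacing=patch_volume.spacing, patient_id="e")
    with pytest.raises(ValueError):
        sample_patches_3d(empty, patch_size=32, n_positive=1, seed=0)
    negs = sample_patches_3d(empty, patch_size=32, n_positive=0,
                             n_negative=2, seed=0)
    assert len(negs) == 2 and all(p.polarity == "negative" for p in negs)
    # volume smaller than the patch is padded, not rejected
    padded = sample_patches_3d(patch_volume, patch_size=64, n_positive=1,
                               n_negative=0, seed=1)
    assert padded[0].image.shape == (64, 64, 64)


# ---------------------------------------------------------------------------
# balanced sampling
# ---------------------------------------------------------------------------

def test_balanced_batches_exact_composition():
    flags = np.array([True] * 100 + [False] * 900)
    batches = balanced_batch_indices(flags, 16, seed=0)
    assert len(batches) == 900 // 8
    for b in batches:
        assert len(b) == 16
        assert flags[b].sum() == 8


def test_balanced_batches_minimal_and_errors():
    batches = balanced_batch_indices([True, False], 2, seed=1)
    assert len(batches) == 1 and sorted(batches[0]) == [0, 1]
    with pytest.raises(ValueError):
        balanced_batch_indices([True, False], 3, seed=0)
    with pytest.raises(ValueError):
        balanced_batch_indices([True, True], 2, seed=0)


@settings(deadline=None, max_examples=20)
@given(n_pos=st.integers(1, 40), n_neg=st.integers(1, 200),
       seed=st.integers(0, 999))
def test_balanced_batches_property(n_pos, n_neg, seed):
    flags = np.array([True] * n_pos + [False] * n_neg)
    for b in balanced_batch_indices(flags, 8, seed=seed):
        assert flags[b].sum() == 4 and (~flags[b]).sum() == 4


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_identity_params_are_a_no_op(small_volume):
    sample, _ = small_volume
    img, msk = sample.image[4][None], sample.mask[4]
    out_i, out_m = augment_2d(img, msk, AugmentParams.identity(), seed=0)
    assert np.array_equal(out_i, img)
    assert np.array_equal(out_m, msk)


def test_vertical_flip_is_an_involution(small_volume):
    sample, _ = small_volume
    img, msk = sample.image[4][None], sample.mask[4]
    flip_only = AugmentParams(rotation_deg=(0, 0), vflip_prob=1.0,
                              brightness_limit=0.0, contrast_limit=0.0,
                              gamma_limit=(1.0, 1.0))
    once_i, once_m = augment_2d(img, msk, flip_only, seed=0)
    twice_i, twice_m = augment_2d(once_i, once_m, flip_only, seed=1)
    assert np.array_equal(twice_i, img)
    assert np.array_equal(twice_m, msk)


def test_rotation_roughly_preserves_mask_area():
    cfg = PhantomConfig(volume_shape=(16, 64, 64), n_nodes_range=(2, 2))
    sample, _ = generate_phantom(cfg, seed=21)
    z = int(np.argmax(sample.mask.sum(axis=(1, 2))))
    img, msk = sample.image[z][None], sample.mask[z]
    rot = AugmentParams(rotation_deg=(10, 10), vflip_prob=0.0,
                        brightness_limit=0.0, contrast_limit=0.0,
                        gamma_limit=(1.0, 1.0))
    _, m1 = augment_2d(img, msk, rot, seed=0)
    assert abs(int(m1.sum()) - int(msk.sum())) <= 0.10 * msk.sum()


def test_geometric_transform_keeps_image_mask_aligned():
    # bright square in the image, same square labelled: after rotation the
    # bright region and the mask must still coincide
    img = np.zeros((1, 64, 64), dtype=np.float32)
    msk = np.zeros((64, 64), dtype=np.uint8)
    img[0, 20:30, 35:45] = 1.0
    msk[20:30, 35:45] = 1
    rot = AugmentParams(rotation_deg=(-10, 10), vflip_prob=0.5,
                        brightness_limit=0.0, contrast_limit=0.0,
                        gamma_limit=(1.0, 1.0))
    for seed in range(5):
        ai, am = augment_2d(img, msk, rot, seed=seed)
        inside = ai[0][am > 0].mean()
        outside = ai[0][am == 0].mean()
        assert inside > 0.8 and outside < 0.05


def test_augment_3d_affine_and_mask_binary(small_volume):
    sample, _ = small_volume
    params = AugmentParams()
    ai, am = augment_3d(sample.image, sample.mask, params, seed=2)
    assert ai.shape == sample.image.shape
    assert set(np.unique(am)) <= {0, 1}
    with pytest.raises(ValueError):
        augment_3d(sample.image, sample.mask * 3, params, seed=0)


def test_augment_params_rotation_bound():
    with pytest.raises(ValueError):
        AugmentParams(rotation_deg=(-30, 30))


# ---------------------------------------------------------------------------
# intensity normalisation
# ---------------------------------------------------------------------------

def test_normalize_window_mapping():
    img = np.array([-200.0, -100.0, 100.0, 300.0, 500.0])
    out = normalize_intensity(img, window=(-100, 300))
    assert np.allclose(out, [0.0, 0.0, 0.5, 1.0, 1.0])
    with pytest.raises(ValueError):
        normalize_intensity(img, window=(10, 10))
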
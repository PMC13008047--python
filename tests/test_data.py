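"""Preprocessing chain, phantom generator, and patient-wise folds."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from lmunet.data import (CaseSeries, CropBox, PhantomSpec, apply_crop_series,
                         compute_crop_box, generate_phantom,
                         largest_diameter_index, make_phantom_dataset,
                         patient_split, preprocess_case, preprocess_slice,
                         read_manifest)


# ---------------------------------------------------------------------------
# Step 1: histogram equalisation


def test_equalisation_constant_image_unchanged():
    img = np.full((8, 8), 77, np.uint8)
    np.testing.assert_array_equal(preprocess_slice(img), img)


def test_equalisation_two_level_mapping():
    img = np.zeros((10, 10), np.uint8)
    img[:5] = 10
    img[5:] = 200
    out = preprocess_slice(img)
    levels = sorted(np.unique(out))
    assert levels[1] == 255
    assert abs(int(levels[0]) - 127) <= 1  # cdf(10) = 0.5 -> ~127


def test_equalisation_preserves_rank(rng):
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    out = preprocess_slice(img)
    a, b = img.ravel(), out.ravel()
    order = np.argsort(a, kind="stable")
    assert np.all(np.diff(b[order].astype(int)) >= 0)
    assert out.dtype == np.uint8


# ---------------------------------------------------------------------------
# Step 2: crop box


def test_crop_box_worked_example():
    mask = np.zeros((64, 64), np.uint8)
    mask[10:21, 30:45] = 1  # rows 10-20, cols 30-44 inclusive
    box = compute_crop_box(mask, margin=5)
    assert (box.row_start, box.row_end, box.col_start, box.col_end) == (5, 26, 25, 50)


def test_crop_box_clipped_at_border():
    mask = np.zeros((16, 16), np.uint8)
    mask[0:3, 2:5] = 1
    box = compute_crop_box(mask, margin=5)
    assert box.row_start == 0
    assert box.col_start == 0


def test_crop_box_zero_margin_is_tight():
    mask = np.zeros((10, 10), np.uint8)
    mask[3:6, 4:8] = 1
    box = compute_crop_box(mask, margin=0)
    assert (box.row_start, box.row_end, box.col_start, box.col_end) == (3, 6, 4, 8)


def test_crop_box_empty_mask_raises():
    with pytest.raises(ValueError, match="foreground"):
        compute_crop_box(np.zeros((8, 8), np.uint8))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16), margin=st.integers(0, 8))
def test_crop_box_matches_bruteforce_scan(seed, margin):
    rng = np.random.default_rng(seed)
    mask = (rng.uniform(size=(24, 30)) > 0.9).astype(np.uint8)
    if not mask.any():
        mask[rng.integers(24), rng.integers(30)] = 1
    box = compute_crop_box(mask, margin=margin)
    rows = [r for r in range(24) if mask[r].any()]
    cols = [c for c in range(30) if mask[:, c].any()]
    assert box.row_start == max(0, min(rows) - margin)
    assert box.row_end == min(24, max(rows) + 1 + margin)
    assert box.col_start == max(0, min(cols) - margin)
    assert box.col_end == min(30, max(cols) + 1 + margin)


def test_crop_box_validates_extent():
    with pytest.raises(ValueError, match="extent"):
        CropBox(5, 5, 0, 3)


# ---------------------------------------------------------------------------
# Steps 3-4: series crop + resize


def _toy_series(rng, n=3, size=64):
    slices, masks = [], []
    for _ in range(n):
        img = rng.integers(0, 256, (size, size)).astype(np.uint8)
        msk = np.zeros((size, size), np.uint8)
        msk[20:40, 25:45] = 1
        slices.append(img)
        masks.append(msk)
    return CaseSeries("p0", slices, masks)


def test_apply_crop_series_output_contract(rng):
    series = _toy_series(rng)
    box = compute_crop_box(series.masks[0], margin=5)
    out = apply_crop_series(series, box, target=224)
    for img, msk in zip(out.slices, out.masks):
        assert img.shape == (224, 224, 3) and img.dtype == np.uint8
        assert msk.shape == (224, 224) and set(np.unique(msk)) <= {0, 1}
        assert msk.any()


def test_apply_crop_series_deterministic(rng):
    series = _toy_series(rng, n=2)
    box = compute_crop_box(series.masks[0], margin=5)
    a = apply_crop_series(series, box)
    b = apply_crop_series(series, box)
    for x, y in zip(a.slices, b.slices):
        np.testing.assert_array_equal(x, y)


def test_apply_crop_series_box_outside_raises(rng):
    series = _toy_series(rng, size=32)
    with pytest.raises(ValueError, match="exceeds"):
        apply_crop_series(series, CropBox(0, 40, 0, 40))


def test_preprocess_case_full_chain(rng):
    out = preprocess_case(_toy_series(rng), margin=5, target=224)
    assert all(s.shape == (224, 224, 3) for s in out.slices)


def test_largest_diameter_selects_biggest_extent():
    small = np.zeros((32, 32), np.uint8)
    small[10:12, 10:12] = 1
    big = np.zeros((32, 32), np.uint8)
    big[2:30, 3:29] = 1
    assert largest_diameter_index([small, big, small]) == 1


def test_case_series_validates_counts():
    with pytest.raises(ValueError, match="counts"):
        CaseSeries("p", [np.zeros((4, 4))], [])


# ---------------------------------------------------------------------------
# phantoms


def test_phantom_seeded_determinism():
    spec = PhantomSpec(image_size=64, seed=9)
    i1, m1 = generate_phantom(spec)
    i2, m2 = generate_phantom(spec)
    np.testing.assert_array_equal(i1, i2)
    np.testing.assert_array_equal(m1, m2)
    assert i1.shape == (64, 64, 3) and i1.dtype == np.uint8
    assert set(np.unique(m1)) <= {0, 1}


def test_phantom_fraction_within_range_over_seeds():
    spec = PhantomSpec(image_size=64)
    lo, hi = spec.foreground_fraction_range
    for seed in range(100):
        _, mask = generate_phantom(replace(spec, seed=seed))
        assert lo <= mask.mean() <= hi


def test_phantom_zero_contrast_gap_hides_foreground():
    spec = PhantomSpec(image_size=96, contrast_gap=0.0, noise_sigma=5.0, seed=3)
    img, mask = generate_phantom(spec)
    gray = img[:, :, 0].astype(float)
    diff = gray[mask == 1].mean() - gray[mask == 0].mean()
    assert abs(diff) < 2.0  # indistinguishable up to noise/bias wiggle


def test_phantom_positive_contrast_visible():
    spec = PhantomSpec(image_size=96, seed=3)
    img, mask = generate_phantom(spec)
    gray = img[:, :, 0].astype(float)
    diff = gray[mask == 1].mean() - gray[mask == 0].mean()
    assert diff > spec.contrast_gap * 0.5


def test_phantom_spec_validation():
    with pytest.raises(ValueError):
        PhantomSpec(foreground_fraction_range=(0.5, 0.1))
    with pytest.raises(ValueError):
        PhantomSpec(noise_sigma=-1)


# ---------------------------------------------------------------------------
# folds and manifests


def test_patient_split_balanced_and_exhaustive():
    folds = patient_split([f"p{i}" for i in range(10)], k=5, seed=0)
    assert len(folds) == 10
    counts = np.bincount(list(folds.values()), minlength=5)
    assert counts.tolist() == [2, 2, 2, 2, 2]


def test_patient_split_seeded_determinism():
    ids = [f"p{i}" for i in range(13)]
    assert patient_split(ids, 5, seed=3) == patient_split(ids, 5, seed=3)
    assert patient_split(ids, 5, seed=3) != patient_split(ids, 5, seed=4)


def test_patient_split_too_few_raises():
    with pytest.raises(ValueError, match="at least"):
        patient_split(["a", "b"], k=5, seed=0)


def test_phantom_dataset_manifest_no_patient_leakage(tmp_path):
    spec = PhantomSpec(image_size=32)
    manifest = make_phantom_dataset(tmp_path, n_patients=6, slices_per_patient=2,
                                    spec=spec, k=3, seed=1)
    rows = read_manifest(manifest)
    assert len(rows) == 12
    fold_of = {}
    for r in rows:
        fold_of.setdefault(r["patient_id"], set()).add(r["fold"])
    assert all(len(folds) == 1 for folds in fold_of.values())
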
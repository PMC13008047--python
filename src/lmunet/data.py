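"""Data pipeline: MRI-style preprocessing, phantoms, patient-wise folds.

The preprocessing chain mirrors how prostate T2-weighted MRI series are
prepared for a 2-D segmentation network:

1. per-slice global histogram equalisation to the 8-bit range;
2. a crop box computed from the patient's largest-diameter mask — the tight
   foreground bounding rectangle expanded by a 5-pixel margin and clipped
   to the image;
3. the same box applied to every slice and mask of that patient;
4. each crop resized to 224x224, images replicated to three channels,
   masks resampled nearest-neighbour and re-binarised.

The synthetic phantom generator stands in for the external dataset in all
tests: it draws a smoothly deformed ellipse on a noisy, intensity-
inhomogeneous background with a small foreground/background intensity gap
and a blurred boundary, emulating the low contrast and fuzzy margins of
prostate MRI.  Phantom datasets are written in the same manifest layout as
preprocessed real data, so the two are interchangeable downstream.

Fold assignment is patient-wise: no patient's slices ever span the
training and validation sides of a fold.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "CaseSeries",
    "CropBox",
    "PhantomSpec",
    "preprocess_slice",
    "compute_crop_box",
    "apply_crop_series",
    "preprocess_case",
    "generate_phantom",
    "patient_split",
    "make_phantom_dataset",
    "read_manifest",
    "write_manifest",
    "load_nifti_case",
]


@dataclass
class CaseSeries:
    """Ordered 2-D slices and matching binary masks for one patient."""

    patient_id: str
    slices: list
    masks: list

    def __post_init__(self):
        if len(self.slices) != len(self.masks):
            raise ValueError("slice and mask counts differ")
        for s, m in zip(self.slices, self.masks):
            if np.asarray(s).shape[:2] != np.asarray(m).shape[:2]:
                raise ValueError("slice/mask shapes differ")


@dataclass(frozen=True)
class CropBox:
    """0-based half-open pixel bounds [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self):
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValueError("crop box must have positive extent")


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of the synthetic low-contrast phantom.

    Intensities live on the 8-bit scale.  ``contrast_gap`` is the mean
    foreground-background gap (small = low contrast); the boundary is
    softened by a Gaussian blur of ``boundary_blur_sigma`` pixels; additive
    Gaussian pixel noise has ``noise_sigma``; a low-frequency bias field of
    amplitude ``bias_amplitude`` emulates coil intensity inhomogeneity.
    """

    image_size: int = 224
    foreground_fraction_range: tuple = (0.05, 0.25)
    contrast_gap: float = 35.0
    boundary_blur_sigma: float = 2.0
    noise_sigma: float = 8.0
    deformation_amplitude: float = 0.15
    background_level: float = 90.0
    bias_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.foreground_fraction_range
        if not (0 < lo < hi < 1):
            raise ValueError("foreground_fraction_range must be inside (0, 1)")
        if min(self.boundary_blur_sigma, self.noise_sigma, self.deformation_amplitude) < 0:
            raise ValueError("sigmas and amplitudes must be nonnegative")


# ---------------------------------------------------------------------------
# preprocessing steps


def preprocess_slice(image):
    """Global histogram equalisation to the 8-bit range (Step 1).

    A constant image has a degenerate histogram and is returned unchanged.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("preprocess_slice expects a 2-D intensity image")
    if img.min() == img.max():
        return img.astype(np.uint8) if img.dtype != np.uint8 else img.copy()
    if img.dtype != np.uint8:
        lo, hi = float(img.min()), float(img.max())
        img = np.round((img.astype(np.float64) - lo) / (hi - lo) * 255).astype(np.uint8)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    lut = np.round(cdf * 255.0).astype(np.uint8)
    return lut[img]


def compute_crop_box(mask, margin=5) -> CropBox:
    """Tight foreground bounding rectangle + margin, clipped to the image (Step 2)."""
    m = np.asarray(mask).astype(bool)
    rows = np.any(m, axis=1)
    cols = np.any(m, axis=0)
    if not rows.any():
        raise ValueError("crop box requires a mask with foreground pixels")
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return CropBox(
        row_start=max(0, int(r0) - margin),
        row_end=min(m.shape[0], int(r1) + 1 + margin),
        col_start=max(0, int(c0) - margin),
        col_end=min(m.shape[1], int(c1) + 1 + margin),
    )


def _crop(arr, box: CropBox):
    h, w = np.asarray(arr).shape[:2]
    if box.row_end > h or box.col_end > w:
        raise ValueError(f"crop box {box} exceeds image shape {(h, w)}")
    return np.asarray(arr)[box.row_start:box.row_end, box.col_start:box.col_end]


def apply_crop_series(series: CaseSeries, box: CropBox, target=224) -> CaseSeries:
    """Crop every slice/mask with the patient box and resize (Steps 3-4)."""
    out_slices, out_masks = [], []
    for img, msk in zip(series.slices, series.masks):
        ci = _crop(img, box).astype(np.float64)
        cm = _crop(msk, box).astype(np.float64)
        ri = resize(ci, (target, target), order=1, preserve_range=True,
                    anti_aliasing=False)
        rm = resize(cm, (target, target), order=0, preserve_range=True,
                    anti_aliasing=False)
        img8 = np.clip(np.round(ri), 0, 255).astype(np.uint8)
        out_slices.append(np.repeat(img8[:, :, None], 3, axis=2))
        out_masks.append((rm > 0.5).astype(np.uint8))
    return CaseSeries(series.patient_id, out_slices, out_masks)


def largest_diameter_index(masks):
    """Index of the mask with the largest foreground bounding-box diagonal."""
    best, best_d = None, -1.0
    for i, m in enumerate(masks):
        m = np.asarray(m).astype(bool)
        if not m.any():
            continue
        box = compute_crop_box(m, margin=0)
        d = math.hypot(box.row_end - box.row_start, box.col_end - box.col_start)
        if d > best_d:
            best, best_d = i, d
    if best is None:
        raise ValueError("no mask in the series has foreground")
    return best


def preprocess_case(series: CaseSeries, margin=5, target=224) -> CaseSeries:
    """Full Steps 1-4 for one patient."""
    equalised = CaseSeries(series.patient_id,
                           [preprocess_slice(s) for s in series.slices],
                           [np.asarray(m).astype(np.uint8) for m in series.masks])
    ref = largest_diameter_index(equalised.masks)
    box = compute_crop_box(equalised.masks[ref], margin=margin)
    return apply_crop_series(equalised, box, target=target)


def load_nifti_case(image_path, mask_path, patient_id=None) -> CaseSeries:
    """Read a NIfTI volume + mask into per-slice arrays (slices on axis 2)."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(image_path)).dataobj).astype(np.float64)
    msk = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes differ")
    pid = patient_id or Path(image_path).name.split(".")[0]
    return CaseSeries(pid,
                      [vol[:, :, i] for i in range(vol.shape[2])],
                      [(msk[:, :, i] > 0).astype(np.uint8) for i in range(msk.shape[2])])


# ---------------------------------------------------------------------------
# synthetic phantoms


def _deformed_ellipse(rng, size, fraction, amplitude):
    """Binary mask of a randomly placed, rotated, radially deformed ellipse."""
    cy, cx = rng.uniform(0.38 * size, 0.62 * size, 2)
    aspect = rng.uniform(0.6, 1.0)
    area = fraction * size * size
    a = math.sqrt(area / (math.pi * aspect))
    b = a * aspect
    theta = rng.uniform(0, math.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y, x = yy - cy, xx - cx
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    rho = np.hypot(xr / a, yr / b)
    phi = np.arctan2(yr / b, xr / a)
    boundary = np.ones_like(phi)
    for k in range(2, 6):
        ck, sk = rng.normal(0, amplitude / 2, 2)
        boundary += ck * np.cos(k * phi) + sk * np.sin(k * phi)
    return rho <= np.maximum(boundary, 0.2)


def generate_phantom(spec: PhantomSpec):
    """One seeded (image, mask) pair; identical seeds are bit-identical.

    Returns an (S, S, 3) uint8 image and an (S, S) uint8 mask.  The mask is
    the pre-blur ellipse region; the image blurs its boundary, adds a
    low-frequency bias field and pixel noise.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    lo, hi = spec.foreground_fraction_range
    mask = None
    for _ in range(64):
        candidate = _deformed_ellipse(rng, size, rng.uniform(lo, hi),
                                      spec.deformation_amplitude)
        frac = candidate.mean()
        if lo <= frac <= hi:
            mask = candidate
            break
    if mask is None:
        raise ValueError("could not draw a foreground fraction inside "
                         f"{spec.foreground_fraction_range} after bounded retries")

    img = spec.background_level + spec.contrast_gap * mask.astype(np.float64)
    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur_sigma)
    # low-frequency intensity inhomogeneity (two random oblique cosines)
    yy, xx = np.mgrid[0:size, 0:size] / size
    for _ in range(2):
        fy, fx = rng.uniform(0.5, 1.5, 2)
        phase = rng.uniform(0, 2 * math.pi)
        img += (spec.bias_amplitude / 2) * np.cos(2 * math.pi * (fy * yy + fx * xx) + phase)
    img += rng.normal(0, spec.noise_sigma, img.shape)
    img8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return np.repeat(img8[:, :, None], 3, axis=2), mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# folds and manifests


def patient_split(cases, k=5, seed=0):
    """Assign each patient to exactly one of k folds (sizes differ by <=1)."""
    ids = [c.patient_id if isinstance(c, CaseSeries) else str(c) for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients for {k} folds, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    return {ids[j]: int(i % k) for i, j in enumerate(order)}


MANIFEST_COLUMNS = ("patient_id", "image_path", "mask_path", "fold")


def write_manifest(path, rows):
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(MANIFEST_COLUMNS)
        for row in rows:
            writer.writerow([row[c] for c in MANIFEST_COLUMNS])


def read_manifest(path):
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = [dict(r) for r in reader]
    for r in rows:
        r["fold"] = int(r["fold"])
    return rows


def make_phantom_dataset(out_dir, n_patients, slices_per_patient, spec: PhantomSpec,
                         k=5, seed=0):
    """Write a phantom dataset in the standard manifest layout.

    Every slice gets its own derived seed so the dataset is reproducible
    from (spec, seed) alone.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    ids = [f"patient{p:03d}" for p in range(n_patients)]
    folds = patient_split(ids, k=k, seed=seed)
    rows = []
    counter = 0
    for pid in ids:
        for s in range(slices_per_patient):
            slice_seed = (seed * 1_000_003 + counter) % (2 ** 31)
            img, msk = generate_phantom(replace(spec, seed=slice_seed))
            ip = out_dir / "images" / f"{pid}_s{s:02d}.png"
            mp = out_dir / "masks" / f"{pid}_s{s:02d}.png"
            Image.fromarray(img).save(ip)
            Image.fromarray(msk * 255).save(mp)
            rows.append({"patient_id": pid, "image_path": str(ip),
                         "mask_path": str(mp), "fold": folds[pid]})
            counter += 1
    manifest = out_dir / "manifest.tsv"
    write_manifest(manifest, rows)
    return manifest


def load_manifest_arrays(rows, image_size=None):
    """Load manifest rows into (images, masks, patient_ids, folds) arrays."""
    images, masks, pids, folds = [], [], [], []
    for r in rows:
        img = np.asarray(Image.open(r["image_path"]))
        msk = (np.asarray(Image.open(r["mask_path"])) > 127).astype(np.uint8)
        if image_size is not None and img.shape[0] != image_size:
            img = np.clip(np.round(resize(img.astype(np.float64), (image_size, image_size, 3),
                                          order=1, preserve_range=True)), 0, 255).astype(np.uint8)
            msk = (resize(msk.astype(np.float64), (image_size, image_size), order=0,
                          preserve_range=True) > 0.5).astype(np.uint8)
        images.append(img)
        masks.append(msk)
        pids.append(r["patient_id"])
        folds.append(int(r["fold"]))
    return np.stack(images), np.stack(masks), pids, np.asarray(folds)
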
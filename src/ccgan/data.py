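"""Dataset I/O, preprocessing, augmentation and synthetic lesion phantoms.

This module stands in for the data plumbing around an imbalanced lesion
segmentation study: paired image/mask files (PNG/TIFF pairs or NIfTI volumes
sliced to 2-D), the preprocessing chain used for MRI-style inputs (resize,
optional CLAHE contrast enhancement, per-channel Z-score), simple geometric
augmentation, k-fold assignment, and a generator of synthetic "lesion on
speckle" images whose foreground fraction mimics the 1-10% regime of real
lesion data.

Images are float64 ``(h, w, c)`` arrays throughout this module; masks are
integer ``(h, w)`` label maps with background 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "ImageSample",
    "SynthConfig",
    "load_dataset",
    "preprocess",
    "augment",
    "rotate",
    "random_crop",
    "generate_synthetic",
    "split_folds",
    "save_dataset",
]


@dataclasses.dataclass
class ImageSample:
    """One image with its ground-truth label map.

    ``fold`` is -1 until :func:`split_folds` assigns it.  ``empty_mask`` flags
    slices whose mask contains no foreground; such slices are retained.
    """

    id: str
    image: np.ndarray  # (h, w, c) float
    mask: np.ndarray  # (h, w) int labels
    fold: int = -1
    empty_mask: bool = False

    def __post_init__(self):
        self.image = np.atleast_3d(np.asarray(self.image, dtype=np.float64))
        self.mask = np.asarray(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape[:2]} does not match "
                f"mask shape {self.mask.shape}"
            )
        if not np.issubdtype(self.mask.dtype, np.integer):
            self.mask = self.mask.astype(np.int64)
        self.empty_mask = not bool(self.mask.any())

    def copy(self) -> "ImageSample":
        return ImageSample(self.id, self.image.copy(), self.mask.copy(), self.fold)


@dataclasses.dataclass
class SynthConfig:
    """Stated world for the synthetic imbalanced-lesion benchmark.

    Defaults are the desk-scale regime: 200 images of 64x64 pixels with a mean
    foreground fraction of 3% — large healthy background, small lesions —
    on a smoothed Gaussian speckle background.
    """

    n_samples: int = 200
    image_size: int = 64
    foreground_fraction: float = 0.03
    n_lesions_range: tuple[int, int] = (1, 3)
    noise_sd: float = 1.0
    blur_sigma: float = 1.0
    lesion_intensity: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0.0 < self.foreground_fraction < 0.5:
            raise ValueError(
                "foreground_fraction must lie in (0, 0.5): the generator models "
                f"minority-foreground data, got {self.foreground_fraction}"
            )
        lo, hi = self.n_lesions_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid n_lesions_range {self.n_lesions_range}")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be non-negative")


# ---------------------------------------------------------------------------
# Loading

_IMG_SUFFIXES = (".png", ".tif", ".tiff")


def _canonical_labels(mask: np.ndarray) -> np.ndarray:
    """Cast a raw mask to consecutive integer labels, keeping 0 = background."""
    mask = np.asarray(mask)
    if mask.ndim == 3:  # RGB(A) mask export: any non-zero channel is foreground
        mask = mask.max(axis=-1)
    values = np.unique(mask)
    if values.size and values[-1] < 16 and np.issubdtype(mask.dtype, np.integer):
        return mask.astype(np.int64)
    # e.g. 0/255 exports: rank-order values, smallest (background) -> 0
    return np.searchsorted(values, mask).astype(np.int64)


def load_dataset(path: str | Path, layout: str = "png_pairs") -> list[ImageSample]:
    """Load image/mask pairs from a directory or a NIfTI volume pair.

    ``png_pairs`` expects ``<stem>.png`` (or .tif/.tiff) next to
    ``<stem>_mask.<ext>``; ``nifti_slices`` expects ``path`` to be the image
    volume with the mask volume at ``<stem>_mask.nii[.gz]``, sliced along the
    last axis into independent 2-D samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path does not exist: {path}")
    if layout == "png_pairs":
        return _load_png_pairs(path)
    if layout == "nifti_slices":
        return _load_nifti_slices(path)
    raise ValueError(f"unknown layout {layout!r}")


def _load_png_pairs(root: Path) -> list[ImageSample]:
    stems = sorted(
        p for p in root.iterdir()
        if p.suffix.lower() in _IMG_SUFFIXES and not p.stem.endswith("_mask")
    )
    if not stems:
        raise FileNotFoundError(f"no image files found under {root}")
    missing: list[str] = []
    samples: list[ImageSample] = []
    for img_path in stems:
        mask_path = None
        for suffix in _IMG_SUFFIXES:
            cand = img_path.with_name(img_path.stem + "_mask" + suffix)
            if cand.exists():
                mask_path = cand
                break
        if mask_path is None:
            missing.append(img_path.stem)
            continue
        image = np.asarray(iio.imread(img_path), dtype=np.float64)
        mask = _canonical_labels(iio.imread(mask_path))
        if image.shape[:2] != mask.shape:
            raise ValueError(
                f"{img_path.stem}: image shape {image.shape[:2]} does not match "
                f"mask shape {mask.shape}"
            )
        samples.append(ImageSample(img_path.stem, image, mask))
    if missing:
        raise FileNotFoundError(
            "missing mask files for stems: " + ", ".join(sorted(missing))
        )
    return samples


def _nifti_mask_path(image_path: Path) -> Path:
    name = image_path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return image_path.with_name(name[: -len(ext)] + "_mask" + ext)
    raise ValueError(f"not a NIfTI file: {image_path}")


def _load_nifti_slices(path: Path) -> list[ImageSample]:
    mask_path = _nifti_mask_path(path)
    if not mask_path.exists():
        raise FileNotFoundError(f"missing mask volume for stem: {mask_path}")
    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    mvol = np.asarray(nib.load(str(mask_path)).get_fdata())
    if vol.shape != mvol.shape:
        raise ValueError(
            f"image volume shape {vol.shape} does not match mask volume shape {mvol.shape}"
        )
    stem = path.name.split(".")[0]
    samples = []
    for z in range(vol.shape[-1]):
        mask = _canonical_labels(np.rint(mvol[..., z]).astype(np.int64))
        samples.append(ImageSample(f"{stem}_z{z:03d}", vol[..., z], mask))
    return samples


# ---------------------------------------------------------------------------
# Preprocessing

def preprocess(
    sample: ImageSample,
    target_size: int = 512,
    clahe: bool = False,
    clip_limit: float = 2.0,
    tile_grid: int = 8,
    replicate_channels: int = 1,
) -> ImageSample:
    """Resize, optionally CLAHE-enhance, then Z-score normalise per channel.

    The image is resized bilinearly to ``target_size`` square and the mask
    with nearest-neighbour (labels stay integral).  CLAHE runs before the
    Z-score; ``clip_limit`` follows the common histogram-clip convention
    (2.0 by default) and is mapped onto skimage's normalised clip limit.
    Constant channels are centred and divided by 1, so blank slices come out
    all-zero instead of NaN.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    image = np.atleast_3d(np.asarray(sample.image, dtype=np.float64))
    if not np.all(np.isfinite(image)):
        raise ValueError(f"{sample.id}: image contains non-finite pixels")
    if image.shape[0] != target_size or image.shape[1] != target_size:
        image = transform.resize(
            image, (target_size, target_size), order=1, mode="reflect",
            anti_aliasing=False, preserve_range=True,
        )
        mask = transform.resize(
            sample.mask.astype(np.float64), (target_size, target_size), order=0,
            mode="constant", anti_aliasing=False, preserve_range=True,
        ).astype(np.int64)
    else:
        mask = sample.mask.copy()
    if replicate_channels > 1 and image.shape[2] == 1:
        image = np.repeat(image, replicate_channels, axis=2)
    if clahe:
        image = _clahe(image, clip_limit, tile_grid)
    mean = image.mean(axis=(0, 1), keepdims=True)
    sd = image.std(axis=(0, 1), keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    out = ImageSample(sample.id, (image - mean) / sd, mask, sample.fold)
    return out


def _clahe(image: np.ndarray, clip_limit: float, tile_grid: int) -> np.ndarray:
    h, w, c = image.shape
    kernel = (max(h // tile_grid, 1), max(w // tile_grid, 1))
    out = np.empty_like(image)
    for ch in range(c):
        plane = image[:, :, ch]
        lo, hi = plane.min(), plane.max()
        scaled = np.zeros_like(plane) if hi <= lo else (plane - lo) / (hi - lo)
        out[:, :, ch] = exposure.equalize_adapthist(
            scaled, kernel_size=kernel, clip_limit=clip_limit / 100.0
        )
    return out


# ---------------------------------------------------------------------------
# Augmentation

def rotate(sample: ImageSample, angle_deg: int) -> ImageSample:
    """Rotate image and mask together by a multiple of 90 degrees (exact)."""
    if angle_deg % 90 != 0:
        raise ValueError("only multiples of 90 degrees are supported (lossless)")
    k = (angle_deg // 90) % 4
    return ImageSample(
        sample.id, np.rot90(sample.image, k, axes=(0, 1)).copy(),
        np.rot90(sample.mask, k, axes=(0, 1)).copy(), sample.fold,
    )


def random_crop(
    sample: ImageSample, crop_size: int, rng: np.random.Generator,
    resize_back: bool = True,
) -> ImageSample:
    """Crop a random window; by default resize back so batch shapes are stable."""
    h, w = sample.mask.shape
    if crop_size > min(h, w):
        raise ValueError(f"crop size {crop_size} exceeds image size {(h, w)}")
    y = int(rng.integers(0, h - crop_size + 1))
    x = int(rng.integers(0, w - crop_size + 1))
    image = sample.image[y : y + crop_size, x : x + crop_size]
    mask = sample.mask[y : y + crop_size, x : x + crop_size]
    out = ImageSample(sample.id, image.copy(), mask.copy(), sample.fold)
    if resize_back and crop_size != h:
        image = transform.resize(out.image, (h, w), order=1, mode="reflect",
                                 anti_aliasing=False, preserve_range=True)
        mask = transform.resize(out.mask.astype(np.float64), (h, w), order=0,
                                mode="constant", preserve_range=True).astype(np.int64)
        out = ImageSample(sample.id, image, mask, sample.fold)
    return out


def augment(
    sample: ImageSample,
    ops: set[str] = frozenset({"rotation"}),
    rng_seed: int = 0,
    crop_fraction: float = 0.75,
) -> ImageSample:
    """Apply seeded random geometric augmentation (identically to image and mask)."""
    unknown = set(ops) - {"random_crop", "rotation"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed)
    out = sample
    if "rotation" in ops:
        out = rotate(out, int(rng.integers(0, 4)) * 90)
    if "random_crop" in ops:
        size = max(int(round(min(out.mask.shape) * crop_fraction)), 1)
        out = random_crop(out, size, rng)
    return out


# ---------------------------------------------------------------------------
# Synthetic phantoms

def generate_synthetic(config: SynthConfig) -> list[ImageSample]:
    """Generate an imbalanced lesion phantom dataset.

    Each image is a smoothed Gaussian speckle background with 1..n elliptical
    "lesions" at a positive intensity offset; the mask is the union of the
    ellipses.  Per-image lesion areas are drawn so the dataset-mean foreground
    fraction tracks ``config.foreground_fraction``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    s = config.image_size
    samples = []
    for i in range(config.n_samples):
        background = rng.standard_normal((s, s))
        if config.blur_sigma > 0:
            background = ndimage.gaussian_filter(background, config.blur_sigma)
            sd = background.std()
            if sd > 0:
                background /= sd  # keep speckle contrast independent of blur
        image = config.noise_sd * background
        mask = np.zeros((s, s), dtype=np.int64)
        n_lesions = int(rng.integers(config.n_lesions_range[0],
                                     config.n_lesions_range[1] + 1))
        # jittered per-image area budget, split across lesions
        total_area = config.foreground_fraction * s * s * rng.uniform(0.8, 1.2)
        shares = rng.dirichlet(np.full(n_lesions, 4.0)) * total_area
        yy, xx = np.mgrid[0:s, 0:s]
        for area in shares:
            ecc = rng.uniform(1.0, 2.5)  # axis ratio
            b = np.sqrt(area / (np.pi * ecc))
            a = ecc * b
            a, b = min(a, s / 4), max(min(b, s / 4), 1.0)
            theta = rng.uniform(0, np.pi)
            margin = int(np.ceil(max(a, b)))
            cy = rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
            cx = rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
            dy, dx = yy - cy, xx - cx
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            mask[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1
        image = image + config.lesion_intensity * mask
        samples.append(ImageSample(f"synth_{i:04d}", image[:, :, None], mask))
    return samples


# ---------------------------------------------------------------------------
# Fold assignment and persistence

def split_folds(samples: list[ImageSample], k: int, seed: int = 0) -> list[ImageSample]:
    """Assign each sample to one of ``k`` folds by a seeded random partition."""
    n = len(samples)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    order = np.random.default_rng(seed).permutation(n)
    out = [s.copy() for s in samples]
    for fold, chunk in enumerate(np.array_split(order, k)):
        for idx in chunk:
            out[idx].fold = fold
    return out


def save_dataset(samples: list[ImageSample], out_dir: str | Path,
                 config: SynthConfig | None = None) -> Path:
    """Write samples in the pair layout plus a JSON manifest.

    Images are min-max scaled to uint8 for PNG (lossy by design; the manifest
    records the provenance, and exact data should be regenerated from config).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in samples:
        img = s.image[:, :, 0] if s.image.shape[2] == 1 else s.image
        lo, hi = img.min(), img.max()
        scaled = np.zeros_like(img) if hi <= lo else (img - lo) / (hi - lo)
        iio.imwrite(out_dir / f"{s.id}.png", (scaled * 255).astype(np.uint8))
        iio.imwrite(out_dir / f"{s.id}_mask.png", s.mask.astype(np.uint8))
    manifest = {
        "n_samples": len(samples),
        "ids": [s.id for s in samples],
        "config": dataclasses.asdict(config) if config is not None else None,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
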
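"""Multi-seed scene preprocessing: grayscale -> threshold -> clean mask -> crops.

A photographed tray of seeds is reduced to individual fixed-size single-seed
crops: luminance conversion, automatic global thresholding (between-class
variance maximization), morphological opening/closing with disk structuring
elements plus hole filling and small-blob rejection, then 8-connected
component labeling with one centroid-centered crop per surviving component.
Touching seeds form a single component; no watershed splitting is attempted.

Also houses the per-class 80/20 ceiling split rule used to partition the
crop dataset into training and validation sets.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationParams", "SeedCrop", "to_grayscale", "binarize",
    "clean_mask", "extract_seeds", "segment_scene", "split_dataset",
    "split_indices", "write_crops",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for scene-to-crop extraction."""

    threshold: str = "otsu_auto"          # "otsu_auto" or "fixed"
    fixed_threshold: int = 128            # used when threshold == "fixed"
    morph_open_radius: int = 3            # px, speckle removal
    morph_close_radius: int = 3           # px, gap bridging
    min_area: int = 400                   # px^2, blob rejection
    crop_size: int = 224
    background_fill: int = 0              # gray level for edge padding

    def __post_init__(self) -> None:
        if self.threshold not in ("otsu_auto", "fixed"):
            raise ValueError(f"unknown threshold method: {self.threshold!r}")
        if not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must be in 0..255")
        if self.crop_size < 32:
            raise ValueError("crop_size must be >= 32")
        if self.morph_open_radius < 0 or self.morph_close_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")


@dataclass
class SeedCrop:
    """One extracted single-seed image in source-scene coordinates."""

    image: np.ndarray          # (crop_size, crop_size, 3) uint8
    centroid: Tuple[float, float]  # (row, col)
    area: int                  # px^2
    source_id: str = ""


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance: 0.299 R + 0.587 G + 0.114 B, rounded to uint8."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    weights = np.array([0.299, 0.587, 0.114])
    gray = rgb.astype(np.float64) @ weights
    return np.rint(gray).clip(0, 255).astype(np.uint8)


def binarize(gray: np.ndarray,
             params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Foreground mask from automatic (or fixed) global thresholding.

    A constant image has no between-class variance to maximize; an empty
    mask is returned with a warning.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if params.threshold == "fixed":
        return (gray > params.fixed_threshold).astype(bool)
    if gray.min() == gray.max():
        warnings.warn("constant image: degenerate threshold, empty mask",
                      stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    return (gray > t).astype(bool)


def clean_mask(mask: np.ndarray,
               params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Morphological opening then closing, hole filling, small-blob removal."""
    mask = np.asarray(mask).astype(bool)
    if params.morph_open_radius > 0:
        mask = morphology.opening(
            mask, morphology.disk(params.morph_open_radius))
    if params.morph_close_radius > 0:
        mask = morphology.closing(
            mask, morphology.disk(params.morph_close_radius))
    mask = ndimage.binary_fill_holes(mask)
    # keep blobs with area >= min_area
    mask = morphology.remove_small_objects(mask, max_size=params.min_area - 1)
    return mask


def _crop_window(rgb: np.ndarray, center: Tuple[float, float], size: int,
                 fill: int) -> np.ndarray:
    h, w = rgb.shape[:2]
    r0 = int(round(center[0])) - size // 2
    c0 = int(round(center[1])) - size // 2
    out = np.full((size, size, 3), fill, dtype=np.uint8)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = rgb[rs:re, cs:ce]
    return out


def extract_seeds(rgb: np.ndarray, mask: np.ndarray,
                  params: SegmentationParams = SegmentationParams(),
                  source_id: str = "") -> List[SeedCrop]:
    """One centroid-centered crop per 8-connected component of the mask.

    Components below min_area are dropped; crops at scene edges are padded
    with background_fill. Crops are ordered row-major by centroid.
    """
    rgb = np.asarray(rgb)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != rgb.shape[:2]:
        raise ValueError("mask and image spatial sizes must match")
    labels = measure.label(mask, connectivity=2)
    crops: List[SeedCrop] = []
    for region in measure.regionprops(labels):
        if region.area < params.min_area:
            continue
        crop = _crop_window(rgb, region.centroid, params.crop_size,
                            params.background_fill)
        crops.append(SeedCrop(image=crop,
                              centroid=(float(region.centroid[0]),
                                        float(region.centroid[1])),
                              area=int(region.area), source_id=source_id))
    crops.sort(key=lambda c: (c.centroid[0], c.centroid[1]))
    return crops


def segment_scene(rgb: np.ndarray,
                  params: SegmentationParams = SegmentationParams(),
                  source_id: str = "") -> List[SeedCrop]:
    """Full pipeline: grayscale, threshold, clean, extract."""
    gray = to_grayscale(rgb)
    mask = clean_mask(binarize(gray, params), params)
    return extract_seeds(rgb, mask, params, source_id=source_id)


def split_dataset(class_counts: Sequence[int],
                  train_fraction: float = 0.8) -> List[Tuple[int, int]]:
    """Per-class (train_n, val_n) under the ceiling 80/20 rule.

    train_n = ceil(train_fraction * count); e.g. 998 -> (799, 199).
    """
    out = []
    for count in class_counts:
        if count < 1:
            raise ValueError("class counts must be >= 1")
        train_n = math.ceil(train_fraction * count)
        out.append((train_n, count - train_n))
    return out


def split_indices(labels: Sequence[int], train_fraction: float = 0.8,
                  rng_seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Random per-class index split honouring the ceiling rule."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng_seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = math.ceil(train_fraction * idx.size)
        train_idx.append(idx[:n_train])
        val_idx.append(idx[n_train:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def write_crops(crops: List[SeedCrop], out_dir, class_name: str = "unknown",
                manifest: Optional[Path] = None) -> List[Path]:
    """Write crops as PNG under out_dir/<class>/ plus a CSV manifest row each."""
    from PIL import Image

    out_dir = Path(out_dir)
    class_dir = out_dir / class_name
    class_dir.mkdir(parents=True, exist_ok=True)
    manifest = Path(manifest) if manifest else out_dir / "manifest.csv"
    new_file = not manifest.exists()
    paths = []
    with manifest.open("a", newline="") as fh:
        writer = csv.writer(fh)
        if new_file:
            writer.writerow(["path", "source_id", "centroid_row",
                             "centroid_col", "area", "class"])
        for i, crop in enumerate(crops):
            name = f"{crop.source_id or 'scene'}_{i:03d}.png"
            path = class_dir / name
            Image.fromarray(crop.image).save(path)
            writer.writerow([str(path), crop.source_id,
                             f"{crop.centroid[0]:.2f}",
                             f"{crop.centroid[1]:.2f}", crop.area, class_name])
            paths.append(path)
    return paths
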
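"""Synthetic seed-image generator.

Stands in for the photographed six-variety seed dataset, which has no
public accession: single-seed crops are rendered as one ellipse per image
(random orientation, class-dependent eccentricity) filled with a
class-specific base colour modulated by a class-specific sinusoidal texture,
over a dark background, with additive Gaussian pixel noise. Multi-seed
scenes place disjoint such ellipses on a near-uniform background and record
the ground-truth mask, centroids and count, so the segmentation pipeline can
be scored against construction.

The appearance model is deliberately simple — classes are separable by mean
colour and texture frequency, which is what makes small-scale training
sanity checks meaningful — and is not a photorealistic seed render.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["ClassAppearance", "SyntheticSpec", "SceneTruth",
           "generate_crop", "generate_dataset", "generate_scene"]


@dataclass(frozen=True)
class ClassAppearance:
    base_rgb: Tuple[int, int, int]
    texture_freq: float              # sinusoid cycles across the ellipse
    ecc_range: Tuple[float, float]   # ellipse eccentricity interval


# six visually distinct variety stand-ins, each with its own texture
# frequency; all bright enough in luminance (>= ~110) that a global
# threshold cleanly separates kernels from the dark tray background
DEFAULT_PALETTE: Tuple[ClassAppearance, ...] = (
    ClassAppearance((215, 180, 70), 2.0, (0.30, 0.55)),
    ClassAppearance((200, 130, 60), 4.0, (0.45, 0.70)),
    ClassAppearance((205, 90, 60), 6.0, (0.30, 0.55)),
    ClassAppearance((225, 205, 120), 8.0, (0.55, 0.80)),
    ClassAppearance((165, 115, 175), 3.0, (0.45, 0.70)),
    ClassAppearance((115, 175, 95), 10.0, (0.55, 0.80)),
)


@dataclass(frozen=True)
class SyntheticSpec:
    n_classes: int = 6
    n_per_class: int = 40
    image_size: int = 224
    scene_size: int = 1024
    seeds_per_scene: int = 12
    noise_sd: float = 6.0            # gray levels
    background_level: int = 12       # dark tray background
    class_palette: Tuple[ClassAppearance, ...] = DEFAULT_PALETTE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_classes > len(self.class_palette):
            raise ValueError("n_classes must fit the palette")
        pairs = {(c.base_rgb, c.texture_freq)
                 for c in self.class_palette[:self.n_classes]}
        if len(pairs) != self.n_classes:
            raise ValueError("classes must have distinct (colour, texture)")


@dataclass
class SceneTruth:
    mask: np.ndarray                     # (H, W) bool
    centroids: List[Tuple[float, float]]  # (row, col) per seed
    count: int


def _ellipse_mask(size_rc: Tuple[int, int], center: Tuple[float, float],
                  a: float, b: float, theta: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size_rc[0], 0:size_rc[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _paint_seed(img: np.ndarray, mask: np.ndarray, app: ClassAppearance,
                center: Tuple[float, float], scale: float, theta: float,
                rng: np.random.Generator) -> None:
    rr, cc = np.nonzero(mask)
    u = ((cc - center[1]) * np.cos(theta) + (rr - center[0]) * np.sin(theta))
    texture = 1.0 + 0.15 * np.sin(2.0 * np.pi * app.texture_freq * u
                                  / (2.0 * scale))
    base = np.array(app.base_rgb, dtype=np.float64)
    img[rr, cc] = np.clip(base[None, :] * texture[:, None], 0, 255)


def generate_crop(class_id: int, spec: SyntheticSpec = SyntheticSpec(),
                  rng: Optional[np.random.Generator] = None,
                  return_mask: bool = False):
    """One (image_size, image_size, 3) uint8 single-seed crop and its label.

    With ``return_mask=True`` also returns the ground-truth ellipse mask.
    """
    if class_id >= spec.n_classes:
        raise ValueError("class_id out of range")
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    app = spec.class_palette[class_id]
    s = spec.image_size
    center = (s / 2 + rng.uniform(-0.04, 0.04) * s,
              s / 2 + rng.uniform(-0.04, 0.04) * s)
    a = rng.uniform(0.30, 0.38) * s
    ecc = rng.uniform(*app.ecc_range)
    b = a * np.sqrt(1.0 - ecc ** 2)
    theta = rng.uniform(0.0, np.pi)
    img = np.full((s, s, 3), spec.background_level, dtype=np.float64)
    mask = _ellipse_mask((s, s), center, a, b, theta)
    _paint_seed(img, mask, app, center, a, theta, rng)
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    out = np.clip(img, 0, 255).astype(np.uint8)
    if return_mask:
        return out, class_id, mask
    return out, class_id


def generate_dataset(spec: SyntheticSpec = SyntheticSpec(),
                     rng: Optional[np.random.Generator] = None
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Balanced crop dataset: (N, S, S, 3) uint8 images, (N,) int labels."""
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    images, labels = [], []
    for cls in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            img, lab = generate_crop(cls, spec, rng)
            images.append(img)
            labels.append(lab)
    return np.stack(images), np.asarray(labels, dtype=np.int64)


def generate_scene(spec: SyntheticSpec = SyntheticSpec(),
                   rng: Optional[np.random.Generator] = None,
                   max_attempts: int = 1000
                   ) -> Tuple[np.ndarray, SceneTruth]:
    """Multi-seed scene of disjoint ellipses with recorded ground truth.

    Placement is rejection-sampled with a safety margin; if a seat cannot be
    found within max_attempts the scene holds fewer seeds and the returned
    count is accurate.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    s = spec.scene_size
    img = np.full((s, s, 3), spec.background_level, dtype=np.float64)
    occupied = np.zeros((s, s), dtype=bool)
    mask = np.zeros((s, s), dtype=bool)
    centroids: List[Tuple[float, float]] = []
    margin = max(4, s // 100)
    seed_scale = 0.07 * s
    placed = 0
    attempts = 0
    while placed < spec.seeds_per_scene and attempts < max_attempts:
        attempts += 1
        cls = int(rng.integers(0, spec.n_classes))
        app = spec.class_palette[cls]
        a = rng.uniform(0.8, 1.2) * seed_scale
        ecc = rng.uniform(*app.ecc_range)
        b = a * np.sqrt(1.0 - ecc ** 2)
        theta = rng.uniform(0.0, np.pi)
        pad = a + margin
        center = (rng.uniform(pad, s - pad), rng.uniform(pad, s - pad))
        m = _ellipse_mask((s, s), center, a, b, theta)
        grown = _ellipse_mask((s, s), center, a + margin, b + margin, theta)
        if (grown & occupied).any():
            continue
        _paint_seed(img, m, app, center, a, theta, rng)
        occupied |= grown
        mask |= m
        rr, cc = np.nonzero(m)
        centroids.append((float(rr.mean()), float(cc.mean())))
        placed += 1
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    scene = np.clip(img, 0, 255).astype(np.uint8)
    return scene, SceneTruth(mask=mask, centroids=centroids, count=placed)
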
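"""Pair-batch construction and affine augmentation for Siamese training.

A training batch is a list of labeled pairs (x1, x2, y): a Bernoulli draw
with success probability ``p_same`` (0.3 by default) decides whether the
pair is same-species (y=1) or different-species (y=0), then the images are
drawn uniformly from the chosen class or classes.  Sampling is with
replacement across batch entries, so small and uneven datasets still yield
full batches.

Augmentation composes, behind a single Bernoulli(0.5) gate per image, a
rotation (integer degrees), optional horizontal/vertical flips, an
isotropic zoom of up to ±10%, and integer pixel shifts of up to ±10 in each
direction.  Out-of-frame pixels are filled with the background value 0
(leaves are bright on dark after preprocessing) and interpolation is
bilinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .data_io import ImageSample, group_by_species

__all__ = [
    "PairExample",
    "SamplingConfig",
    "AugmentationConfig",
    "as_class_index",
    "make_pair_batch",
    "augment",
]


@dataclass
class PairExample:
    """A labeled image pair; y = 1 iff both images share a species."""

    x1: np.ndarray
    x2: np.ndarray
    y: int
    species1: str | None = None
    species2: str | None = None


@dataclass(frozen=True)
class SamplingConfig:
    batch_size: int = 32
    p_same: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_same <= 1):
            raise ValueError("p_same must lie in [0,1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameter ranges for the stochastic affine transform.

    Each draw is uniform over the stated range: rotation in
    [0, rotation_degrees] integer degrees, zoom in ±``zoom`` percent,
    shifts in ±``shift_x``/±``shift_y`` integer pixels; flips, when
    enabled, are applied with probability 1/2 each.  The whole composed
    transform is applied with probability ``gate_probability``, otherwise
    the image passes through untouched.
    """

    rotation_degrees: int = 360
    vertical_flip: bool = True
    horizontal_flip: bool = True
    zoom: float = 10.0
    shift_x: int = 10
    shift_y: int = 10
    gate_probability: float = 0.5

    def __post_init__(self):
        if not (0 <= self.rotation_degrees <= 360):
            raise ValueError("rotation_degrees must lie in [0,360]")
        if not (0 <= self.zoom <= 10) or abs(self.shift_x) > 10 or abs(self.shift_y) > 10:
            raise ValueError("zoom and shifts must lie within ±10")
        if not (0 <= self.gate_probability <= 1):
            raise ValueError("gate_probability must lie in [0,1]")


def as_class_index(training_set) -> dict[str, list[np.ndarray]]:
    """Normalize a dataset to {species: [image, ...]}.

    Accepts either that mapping directly or a flat list of ImageSamples.
    """
    if isinstance(training_set, dict):
        return {k: list(v) for k, v in training_set.items()}
    if training_set and isinstance(training_set[0], ImageSample):
        return {k: [s.image for s in v]
                for k, v in group_by_species(training_set).items()}
    raise TypeError("training_set must be a {label: images} dict or list of ImageSample")


def make_pair_batch(training_set, cfg: SamplingConfig,
                    rng: np.random.Generator) -> list[PairExample]:
    """Draw ``cfg.batch_size`` labeled pairs from a class-indexed collection."""
    index = as_class_index(training_set)
    labels = sorted(index)
    if not labels:
        raise ValueError("empty training set")
    # positive pairs need two distinct images, so their class is drawn
    # among classes holding at least 2
    positive_ok = [l for l in labels if len(index[l]) >= 2]
    batch: list[PairExample] = []
    for _ in range(cfg.batch_size):
        same = rng.random() < cfg.p_same
        if same:
            if not positive_ok:
                raise ValueError("no class has 2+ images; cannot draw a positive pair")
            cls = positive_ok[rng.integers(len(positive_ok))]
            imgs = index[cls]
            i, j = rng.choice(len(imgs), size=2, replace=False)
            batch.append(PairExample(imgs[i], imgs[j], 1, cls, cls))
        else:
            if len(labels) < 2:
                raise ValueError("need at least 2 classes to draw a negative pair")
            a, b = rng.choice(len(labels), size=2, replace=False)
            ca, cb = labels[a], labels[b]
            batch.append(PairExample(
                index[ca][rng.integers(len(index[ca]))],
                index[cb][rng.integers(len(index[cb]))],
                0, ca, cb))
    return batch


def _compose(matrices):
    out = np.eye(3)
    for m in matrices:
        out = out @ m
    return out


def apply_affine(image: np.ndarray, angle_degrees: float = 0.0,
                 flip_h: bool = False, flip_v: bool = False,
                 scale: float = 1.0, shift_x: int = 0, shift_y: int = 0) -> np.ndarray:
    """Apply one composed affine transform about the image center.

    Rotation, flips and zoom act about the center; shifts are applied last.
    Bilinear interpolation, constant 0 fill, output shape equals input.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    angle = np.deg2rad(angle_degrees)

    def translate(x, y):
        m = np.eye(3)
        m[0, 2], m[1, 2] = x, y
        return m

    rot = np.eye(3)
    rot[0, 0] = rot[1, 1] = np.cos(angle)
    rot[0, 1], rot[1, 0] = -np.sin(angle), np.sin(angle)
    flip = np.diag([-1.0 if flip_h else 1.0, -1.0 if flip_v else 1.0, 1.0])
    zoom = np.diag([scale, scale, 1.0])

    # forward map in (x, y) homogeneous coordinates
    forward = _compose([translate(cx + shift_x, cy + shift_y), rot, flip, zoom,
                        translate(-cx, -cy)])
    tform = AffineTransform(matrix=forward)
    out = warp(image.astype(np.float64), tform.inverse, order=1,
               mode="constant", cval=0.0, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(image.dtype)


def augment(image: np.ndarray, cfg: AugmentationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Stochastically apply the composed affine transform to one image.

    The gate draw and every parameter draw consume the supplied generator,
    so a seeded stream reproduces the augmentation sequence exactly.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if rng.random() >= cfg.gate_probability:
        return image
    return apply_affine(
        image,
        angle_degrees=int(rng.integers(0, cfg.rotation_degrees + 1)),
        flip_h=bool(cfg.horizontal_flip and rng.random() < 0.5),
        flip_v=bool(cfg.vertical_flip and rng.random() < 0.5),
        scale=1.0 + rng.uniform(-cfg.zoom, cfg.zoom) / 100.0,
        shift_x=int(rng.integers(-cfg.shift_x, cfg.shift_x + 1)),
        shift_y=int(rng.integers(-cfg.shift_y, cfg.shift_y + 1)))
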
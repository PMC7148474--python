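"""Loading class-per-folder leaf datasets and building experiment splits.

Datasets on disk follow the common one-folder-per-species layout.  Images
are decoded with Pillow, converted to grayscale, resized, and scaled to
[0, 1] floats.  White-background scans can be intensity-inverted so every
dataset presents a bright leaf on a dark background, which also makes the
zero fill used by affine augmentation blend with the background.

Splitting follows a fixed protocol: a test pool P of ``n_test_per_species``
images per species is drawn first and never changes between experiments;
the remainder is divided 80/20 into training (T) and validation (V) pools.
An experiment E_i then subsamples i images per species from T and V in the
same 80/20 proportion, e.g. E10 uses 8 training and 2 validation images per
species.  All draws are without replacement and deterministic in the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "ImageSample",
    "DatasetSplit",
    "ExperimentConfig",
    "load_dataset",
    "make_split",
    "make_experiment",
]

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclass
class ImageSample:
    """One grayscale leaf image in [0,1] with its species label."""

    image: np.ndarray
    species_id: str
    source_path: str


@dataclass
class DatasetSplit:
    """The three disjoint pools: P (test), T (training), V (validation)."""

    P: list[ImageSample]
    T: list[ImageSample]
    V: list[ImageSample]


@dataclass(frozen=True)
class ExperimentConfig:
    """One E_i experiment: i images/species split train_fraction : rest."""

    images_per_species: int | str  # an integer or "all"
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0,1)")
        i = self.images_per_species
        if i != "all" and (not isinstance(i, (int, np.integer)) or i < 2):
            raise ValueError("images_per_species must be >= 2 or 'all'")


def load_image(path, target_size: int, invert_background: bool = False) -> np.ndarray:
    with Image.open(path) as im:
        im = im.convert("L").resize((target_size, target_size), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return 1.0 - arr if invert_background else arr


def load_dataset(root, target_size: int = 224,
                 invert_background: bool = False) -> list[ImageSample]:
    """Read a class-per-folder image tree into a list of ImageSamples.

    Unreadable files are skipped with a warning; an empty species folder is
    an error.  Iteration order is sorted, so the result is independent of
    filesystem listing order.
    """
    root = Path(root)
    species_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not species_dirs:
        raise ValueError(f"no species folders under {root}")
    samples: list[ImageSample] = []
    for sdir in species_dirs:
        files = sorted(p for p in sdir.iterdir()
                       if p.suffix.lower() in IMAGE_SUFFIXES)
        loaded = 0
        for f in files:
            try:
                img = load_image(f, target_size, invert_background)
            except OSError as exc:  # undecodable image
                logger.warning("skipping unreadable image %s: %s", f, exc)
                continue
            samples.append(ImageSample(img, sdir.name, str(f.relative_to(root))))
            loaded += 1
        if loaded == 0:
            raise ValueError(f"species folder {sdir} contains no readable images")
    return samples


def group_by_species(samples) -> dict[str, list[ImageSample]]:
    groups: dict[str, list[ImageSample]] = {}
    for s in samples:
        groups.setdefault(s.species_id, []).append(s)
    return groups


def make_split(samples, n_test_per_species: int = 10,
               train_fraction: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Draw the fixed test pool P and divide the rest into T and V.

    Per species: ``n_test_per_species`` images go to P (without replacement),
    then round(train_fraction * remainder) to T and the rest to V.  Ordering
    inside each species is canonicalized by source_path before the seeded
    shuffle, so membership does not depend on input order.
    """
    rng = np.random.default_rng(seed)
    P: list[ImageSample] = []
    T: list[ImageSample] = []
    V: list[ImageSample] = []
    groups = group_by_species(samples)
    for species in sorted(groups):
        group = sorted(groups[species], key=lambda s: s.source_path)
        if len(group) <= n_test_per_species:
            raise ValueError(
                f"species {species} has {len(group)} images, needs more than "
                f"{n_test_per_species} to form a test pool")
        order = rng.permutation(len(group))
        shuffled = [group[i] for i in order]
        P.extend(shuffled[:n_test_per_species])
        rest = shuffled[n_test_per_species:]
        n_train = int(round(train_fraction * len(rest)))
        T.extend(rest[:n_train])
        V.extend(rest[n_train:])
    return DatasetSplit(P=P, T=T, V=V)


def make_experiment(split: DatasetSplit, cfg: ExperimentConfig):
    """Subsample the E_i training/validation sets from the T and V pools.

    Returns ``(Tn, Vn, P)``; P passes through unchanged so every experiment
    is scored on the same test images.
    """
    if cfg.images_per_species == "all":
        return list(split.T), list(split.V), list(split.P)
    i = int(cfg.images_per_species)
    n_train = int(round(cfg.train_fraction * i))
    n_val = i - n_train
    if n_train < 1 or n_val < 1:
        raise ValueError(f"i={i} leaves an empty train or validation set")
    rng = np.random.default_rng(cfg.seed)
    t_groups = group_by_species(split.T)
    v_groups = group_by_species(split.V)
    Tn: list[ImageSample] = []
    Vn: list[ImageSample] = []
    for species in sorted(t_groups):
        tg = sorted(t_groups[species], key=lambda s: s.source_path)
        vg = sorted(v_groups.get(species, []), key=lambda s: s.source_path)
        if len(tg) < n_train or len(vg) < n_val:
            raise ValueError(
                f"species {species}: need {n_train} train / {n_val} val images, "
                f"pools hold {len(tg)} / {len(vg)}")
        Tn.extend(tg[j] for j in rng.choice(len(tg), size=n_train, replace=False))
        Vn.extend(vg[j] for j in rng.choice(len(vg), size=n_val, replace=False))
    return Tn, Vn, list(split.P)
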
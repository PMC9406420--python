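"""Deterministic 8-fold rotation/flip augmentation and train/validation splitting.

Each ROI is expanded into the 8 elements of the dihedral group D4: the four
90-degree counter-clockwise rotations of the original and of its horizontal
mirror.  Rotations by 90-degree multiples are exact grid permutations, so the
image and its mask transform without any interpolation loss and mask
foreground counts are preserved exactly.  Augmented pools are split into
train/validation as floor(f*N) / remainder with a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np

from .errors import ConfigError, ShapeError
from .preprocess import RoiSample

__all__ = ["AugmentationVariant", "SplitSpec", "VARIANTS", "apply_variant",
           "augment_eightfold", "split_train_val"]

T = TypeVar("T")


@dataclass(frozen=True)
class AugmentationVariant:
    """One D4 grid symmetry: counter-clockwise rotation plus optional horizontal mirror."""

    rotation: int  # degrees CCW, one of 0/90/180/270
    flipped: bool

    def __post_init__(self):
        if self.rotation not in (0, 90, 180, 270):
            raise ConfigError(f"rotation must be a multiple of 90 in [0,270], got {self.rotation}")

    def apply(self, grid: np.ndarray) -> np.ndarray:
        """Apply this variant to a square 2D grid (flip first, then rotate)."""
        if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
            raise ShapeError(f"augmentation needs a square 2D grid, got {grid.shape}")
        out = grid[:, ::-1] if self.flipped else grid
        return np.rot90(out, k=self.rotation // 90).copy()

    def invert(self, grid: np.ndarray) -> np.ndarray:
        """Undo this variant (rotate back, then unflip)."""
        out = np.rot90(grid, k=-(self.rotation // 90))
        return (out[:, ::-1] if self.flipped else out).copy()


#: The 8 distinct variants, identity first.
VARIANTS: tuple[AugmentationVariant, ...] = tuple(
    AugmentationVariant(rotation=rot, flipped=fl)
    for fl in (False, True) for rot in (0, 90, 180, 270)
)


def apply_variant(sample: RoiSample, variant: AugmentationVariant) -> RoiSample:
    """Apply one variant jointly to a sample's image and mask."""
    return RoiSample(
        image=variant.apply(sample.image),
        mask=variant.apply(sample.mask),
        source_id=sample.source_id,
        dataset_tag=sample.dataset_tag,
    )


def augment_eightfold(sample: RoiSample) -> list[tuple[AugmentationVariant, RoiSample]]:
    """Expand one ROI into its 8 rotation/flip variants (tagged, identity included)."""
    if sample.image.shape[0] != sample.image.shape[1]:
        raise ShapeError("eightfold augmentation requires square inputs")
    return [(v, apply_variant(sample, v)) for v in VARIANTS]


@dataclass(frozen=True)
class SplitSpec:
    """Seeded train/validation split with |train| = floor(train_fraction * N)."""

    train_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError(f"train_fraction must lie in (0,1), got {self.train_fraction}")


def split_train_val(samples: Sequence[T], spec: SplitSpec) -> tuple[list[T], list[T]]:
    """Shuffle deterministically and split into (train, validation).

    The two parts are disjoint and exhaustive; the train side has exactly
    floor(train_fraction * N) items.
    """
    spec.validate()
    n = len(samples)
    if n < 2:
        raise ConfigError(f"need at least 2 samples to split, got {n}")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    train = [samples[i] for i in order[:n_train]]
    val = [samples[i] for i in order[n_train:]]
    return train, val
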
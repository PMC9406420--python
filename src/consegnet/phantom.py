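"""Synthetic mammogram-like phantoms with paired ground-truth masks.

Real mammographic ROI datasets are large, partly private, and need manual
annotation.  This module generates small grayscale phantoms that reproduce the
statistical features the segmentation pipeline relies on: a textured,
low-contrast background whose intensities occupy a compressed dynamic range
(so adaptive histogram equalization has a measurable effect), and one or more
blob-like lesions with irregular boundaries sitting slightly above the
background intensity.  Every phantom is deterministic in its seed, so the
whole pipeline is testable without any downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError
from . import imgio

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion phantom.

    Attributes
    ----------
    seed:
        RNG seed; the same spec always renders bit-identical output.
    size:
        Image side length in pixels (square images).
    n_lesions:
        Number of lesions to embed; 0 gives a pure background with an
        empty mask.
    lesion_radius_range:
        (min, max) base radius in pixels, sampled uniformly per lesion.
    lesion_contrast:
        Additive intensity offset of lesion over background, in [0, 0.5].
    boundary_irregularity:
        Amplitude of the low-frequency radial perturbation of the lesion
        outline, as a fraction of the base radius; 0 gives perfect disks.
    background_texture_scale:
        Correlation length (pixels) of the smoothed random background field.
    noise_sd:
        Standard deviation of the additive Gaussian pixel noise.
    dynamic_range:
        (low, high) interval the background is rescaled into; compressed
        ranges such as (0.3, 0.7) emulate the flat histograms CLAHE is
        meant to expand.
    """

    seed: int = 0
    size: int = 256
    n_lesions: int = 1
    lesion_radius_range: tuple[float, float] = (20.0, 60.0)
    lesion_contrast: float = 0.18
    boundary_irregularity: float = 0.3
    background_texture_scale: float = 16.0
    noise_sd: float = 0.02
    dynamic_range: tuple[float, float] = (0.3, 0.7)

    def validate(self) -> None:
        lo, hi = self.dynamic_range
        rmin, rmax = self.lesion_radius_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"dynamic_range must satisfy 0 <= low < high <= 1, got {self.dynamic_range}")
        if rmin < 2 or rmax < rmin:
            raise ConfigError(f"lesion_radius_range must satisfy 2 <= min <= max, got {self.lesion_radius_range}")
        if self.size < 8:
            raise ConfigError(f"size must be >= 8, got {self.size}")
        if self.n_lesions < 0:
            raise ConfigError("n_lesions must be >= 0")
        if not (0.0 <= self.lesion_contrast <= 0.5):
            raise ConfigError(f"lesion_contrast must lie in [0, 0.5], got {self.lesion_contrast}")
        if self.boundary_irregularity < 0:
            raise ConfigError("boundary_irregularity must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class PhantomPair:
    """One rendered phantom: image in [0,1], binary mask, and its spec."""

    image: np.ndarray
    mask: np.ndarray
    spec: PhantomSpec


def _lesion_support(size: int, center: tuple[float, float], base_radius: float,
                    irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one lesion: a disk whose outline is pushed outward by a
    low-frequency radial perturbation.

    The perturbation is nonnegative, so the support always contains the
    base disk: pixel count is bounded below by ~pi*r^2 and above by
    ~pi*(r*(1+2a))^2 with a <= 0.45.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center[0]
    dx = xx - center[1]
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    # few random harmonics, shifted so the perturbation is outward-only
    amp = min(0.45, 0.5 * irregularity)
    pert = np.zeros_like(theta)
    for k in range(2, 6):
        a_k = rng.normal(0.0, 1.0) / k
        p_k = rng.uniform(0.0, 2.0 * np.pi)
        pert += a_k * np.cos(k * theta + p_k)
    if amp > 0 and np.ptp(pert) > 0:
        pert = amp * (pert - pert.min()) / np.ptp(pert) * 2.0  # in [0, 2*amp]
    else:
        pert = np.zeros_like(theta)
    radius = base_radius * (1.0 + pert)
    return dist <= radius


def generate_phantom(spec: PhantomSpec) -> PhantomPair:
    """Render one phantom image/mask pair deterministically from its spec.

    The background is a smoothed random field rescaled into
    ``spec.dynamic_range``; lesions add ``lesion_contrast`` (with a softened
    rim) on top of it; Gaussian noise is applied last and the image is
    clipped back into [0, 1].  The mask is exactly the union of the lesion
    supports, before any smoothing or noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.size

    field_ = rng.normal(0.0, 1.0, size=(n, n))
    field_ = gaussian_filter(field_, sigma=max(spec.background_texture_scale, 1e-3) / 2.0)
    lo, hi = spec.dynamic_range
    span = np.ptp(field_)
    if span > 0:
        background = lo + (hi - lo) * (field_ - field_.min()) / span
    else:
        background = np.full((n, n), 0.5 * (lo + hi))

    mask = np.zeros((n, n), dtype=bool)
    rmin, rmax = spec.lesion_radius_range
    amp = min(0.45, 0.5 * spec.boundary_irregularity)
    for _ in range(spec.n_lesions):
        base_r = rng.uniform(rmin, min(rmax, n / 2.5))
        margin = base_r * (1.0 + 2.0 * amp) + 2.0
        margin = min(margin, n / 2.0 - 1.0)
        cy = rng.uniform(margin, n - margin)
        cx = rng.uniform(margin, n - margin)
        mask |= _lesion_support(n, (cy, cx), base_r, spec.boundary_irregularity, rng)

    image = background.copy()
    if mask.any() and spec.lesion_contrast > 0:
        bump = gaussian_filter(mask.astype(float), sigma=1.5)
        bump = np.clip(bump / max(bump.max(), 1e-9), 0.0, 1.0)
        bump = np.maximum(bump, mask)  # full weight everywhere inside the support
        # lesions sit on tissue: lift any local background dip to the global
        # mean before adding the contrast, so every lesion pixel ends at least
        # lesion_contrast above the mean background level (smooth rim outside)
        lift = np.maximum(background.mean() - background, 0.0)
        image = image + bump * (lift + spec.lesion_contrast)

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(n, n))
    image = np.clip(image, 0.0, 1.0)
    return PhantomPair(image=image, mask=mask.astype(np.uint8), spec=spec)


def generate_dataset(n: int, base_seed: int, spec_template: PhantomSpec,
                     out_dir: str | Path, *, split: str = "train",
                     dataset_tag: str = "phantom",
                     manifest_name: str = "manifest.csv") -> Path:
    """Write ``n`` phantom pairs as PNGs plus a CSV manifest; return the manifest path.

    Item ``i`` uses seed ``base_seed + i``, so regenerating with the same
    arguments is byte-identical.  Manifest columns: image_path, mask_path,
    split, dataset_tag, source_id (paths relative to the manifest).
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    spec_template.validate()
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n):
        spec = replace(spec_template, seed=base_seed + i)
        pair = generate_phantom(spec)
        source_id = f"{dataset_tag}_{base_seed + i:06d}"
        img_rel = f"images/{source_id}.png"
        msk_rel = f"masks/{source_id}_mask.png"
        imgio.write_image(out_dir / img_rel, pair.image)
        imgio.write_mask(out_dir / msk_rel, pair.mask)
        rows.append((img_rel, msk_rel, split, dataset_tag, source_id))

    manifest = out_dir / manifest_name
    lines = ["image_path,mask_path,split,dataset_tag,source_id"]
    lines += [",".join(r) for r in rows]
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
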
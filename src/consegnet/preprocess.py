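"""ROI standardization and CLAHE contrast enhancement.

Tumor ROIs arrive as manually drawn bounding boxes on grayscale images of
arbitrary size.  ``prepare_roi`` crops and resamples them to the model's fixed
256x256 input grid (bilinear for intensities, nearest-neighbor for masks so
they stay strictly binary).  ``apply_clahe`` runs contrast-limited adaptive
histogram equalization: per-tile histogram equalization whose per-bin mass is
capped at ``clip_limit`` times the mean bin mass (excess redistributed
uniformly), with the tile mappings blended bilinearly across the image.
Mammographic ROIs tend to occupy a compressed intensity range; CLAHE expands
local contrast without the noise amplification of plain global equalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, DataError, ShapeError

__all__ = ["RoiSample", "ClaheParams", "prepare_roi", "apply_clahe"]

ROI_SIZE = 256
_NBINS = 256  # 8-bit internal quantization


@dataclass
class RoiSample:
    """One standardized ROI: image in [0,1] and binary mask on the same grid."""

    image: np.ndarray
    mask: np.ndarray
    source_id: str = ""
    dataset_tag: str = ""

    def validate(self, size: int = ROI_SIZE) -> None:
        if self.image.shape != (size, size) or self.mask.shape != (size, size):
            raise ShapeError(
                f"RoiSample expects {size}x{size} image and mask, got {self.image.shape} / {self.mask.shape}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise DataError("RoiSample mask must be binary")


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE parameters: contrast clip limit and equalization tile grid.

    ``clip_limit`` is expressed as a multiple of the mean per-bin histogram
    mass of a tile (the common convention in medical-imaging toolkits);
    larger values allow more contrast amplification, and in the limit the
    method degenerates to plain tile-wise histogram equalization.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def validate(self) -> None:
        if self.clip_limit <= 0:
            raise ConfigError(f"clip_limit must be > 0, got {self.clip_limit}")
        if min(self.tile_grid) < 1:
            raise ConfigError(f"tile_grid entries must be >= 1, got {self.tile_grid}")


def prepare_roi(image: np.ndarray, mask: np.ndarray,
                bbox: tuple[int, int, int, int],
                *, size: int = ROI_SIZE,
                source_id: str = "", dataset_tag: str = "") -> RoiSample:
    """Crop image and mask to a half-open bbox and resample to ``size`` x ``size``.

    The image is resampled bilinearly; the mask by nearest neighbor and
    re-binarized, so output masks are strictly {0,1}.  A crop already at the
    target size passes through untouched.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ShapeError(f"image {image.shape} and mask {mask.shape} differ")
    r0, c0, r1, c1 = bbox
    h, w = image.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ShapeError(f"bbox {bbox} invalid for image of shape {image.shape}")

    img_crop = image[r0:r1, c0:c1]
    msk_crop = mask[r0:r1, c0:c1]
    if img_crop.shape == (size, size):
        out_img = img_crop.copy()
        out_msk = (msk_crop > 0).astype(np.uint8)
    else:
        out_img = _sk_resize(img_crop, (size, size), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
        out_msk = _sk_resize(msk_crop.astype(np.float64), (size, size), order=0,
                             mode="edge", anti_aliasing=False, preserve_range=True)
        out_msk = (out_msk > 0.5).astype(np.uint8)
    return RoiSample(image=np.clip(out_img, 0.0, 1.0), mask=out_msk,
                     source_id=source_id, dataset_tag=dataset_tag)


def _tile_edges(n: int, tiles: int) -> np.ndarray:
    return np.round(np.linspace(0, n, tiles + 1)).astype(int)


def _tile_mapping(levels: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization lookup table (256 -> [0,1]) for one tile's quantized levels."""
    hist = np.bincount(levels.ravel(), minlength=_NBINS).astype(np.float64)
    npix = hist.sum()
    clim = max(clip_limit * npix / _NBINS, 1.0)
    excess = np.maximum(hist - clim, 0.0).sum()
    hist = np.minimum(hist, clim) + excess / _NBINS
    cdf = np.cumsum(hist)
    nonzero = np.nonzero(hist)[0]
    cdf_min = cdf[nonzero[0]] if nonzero.size else 0.0
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # single occupied level: identity mapping keeps it constant
        return np.arange(_NBINS, dtype=np.float64) / (_NBINS - 1)
    return np.clip((cdf - cdf_min) / denom, 0.0, 1.0)


def apply_clahe(image: np.ndarray, params: ClaheParams = ClaheParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0,1] image.

    The image is quantized to 256 levels; each tile of the grid gets a
    clip-limited equalization lookup table; every output pixel bilinearly
    blends the tables of the (up to) four nearest tile centers.  Output has
    the input's shape and stays in [0,1].
    """
    params.validate()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ShapeError(f"apply_clahe expects a 2D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise DataError("apply_clahe: non-finite pixels")

    h, w = image.shape
    tr, tc = params.tile_grid
    tr, tc = min(tr, h), min(tc, w)
    q = np.clip((image * _NBINS).astype(int), 0, _NBINS - 1)

    rows = _tile_edges(h, tr)
    cols = _tile_edges(w, tc)
    maps = np.empty((tr, tc, _NBINS))
    for i in range(tr):
        for j in range(tc):
            maps[i, j] = _tile_mapping(q[rows[i]:rows[i + 1], cols[j]:cols[j + 1]],
                                       params.clip_limit)

    cy = (rows[:-1] + rows[1:]) / 2.0
    cx = (cols[:-1] + cols[1:]) / 2.0

    def axis_weights(n: int, centers: np.ndarray):
        pos = np.arange(n, dtype=np.float64)
        hi = np.clip(np.searchsorted(centers, pos), 0, len(centers) - 1)
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        wgt = np.where(span > 0, (pos - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
        return lo, hi, np.clip(wgt, 0.0, 1.0)

    ry0, ry1, wy = axis_weights(h, cy)
    rx0, rx1, wx = axis_weights(w, cx)
    wy = wy[:, None]
    wx = wx[None, :]

    out = ((1 - wy) * (1 - wx) * maps[ry0[:, None], rx0[None, :], q]
           + (1 - wy) * wx * maps[ry0[:, None], rx1[None, :], q]
           + wy * (1 - wx) * maps[ry1[:, None], rx0[None, :], q]
           + wy * wx * maps[ry1[:, None], rx1[None, :], q])
    return np.clip(out, 0.0, 1.0)
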
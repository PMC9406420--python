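"""Grayscale PNG/TIFF image and mask I/O, plus CSV manifest handling.

Images are stored as 16-bit grayscale PNG (intensities in [0,1] scaled to
0..65535); masks as 8-bit PNG with {0,255} encoding {0,1}.  Manifests are
plain CSV with paths relative to the manifest file.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError, DependencyError

MANIFEST_COLUMNS = ["image_path", "mask_path", "split", "dataset_tag", "source_id"]


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image in [0,1] as 16-bit grayscale PNG/TIFF."""
    arr = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"non-finite pixels writing {path}")
    quant = np.clip(np.round(arr * 65535.0), 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), quant)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image into float64 [0,1]."""
    path = Path(path)
    if not path.exists():
        raise DependencyError(f"missing image file: {path}")
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:  # collapse accidental RGB
        raw = raw[..., 0]
    info = np.iinfo(raw.dtype) if raw.dtype.kind in "iu" else None
    if info is not None:
        return raw.astype(np.float64) / info.max
    return np.clip(raw.astype(np.float64), 0.0, 1.0)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG with {0,255}."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise DataError(f"mask is not binary writing {path}")
    iio.imwrite(Path(path), (arr.astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to {0,1} uint8."""
    path = Path(path)
    if not path.exists():
        raise DependencyError(f"missing mask file: {path}")
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return (raw > (np.iinfo(raw.dtype).max // 2 if raw.dtype.kind in "iu" else 0.5)).astype(np.uint8)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load a manifest CSV, checking the required columns are present."""
    path = Path(path)
    if not path.exists():
        raise DependencyError(f"missing manifest: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} lacks columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def load_pairs(manifest: str | Path, df: pd.DataFrame | None = None):
    """Yield (image, mask, row) for every manifest row, resolving relative paths."""
    manifest = Path(manifest)
    if df is None:
        df = read_manifest(manifest)
    base = manifest.parent
    for _, row in df.iterrows():
        yield read_image(base / row["image_path"]), read_mask(base / row["mask_path"]), row
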
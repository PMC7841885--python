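"""Raster and mask input/output.

Images are 8-bit PNG/TIFF/BMP, 1 or 3 channels; instance label masks are
written as 16-bit single-channel PNG/TIFF (0 = background).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "read_mask", "write_mask", "write_image", "write_overlay"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit raster; drops a trailing alpha channel if present."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit image, got dtype {arr.dtype}")
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    """Read an instance label mask (8- or 16-bit single channel) as int32."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: label masks must be single-channel")
    return arr.astype(np.int32)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("label mask does not fit a 16-bit image")
    iio.imwrite(Path(path), mask.astype(np.uint16))


def write_overlay(path: str | Path, img: np.ndarray, mask: np.ndarray) -> None:
    """Write the image with nucleus boundaries drawn in yellow."""
    from skimage.segmentation import find_boundaries

    from .preprocessing import to_grayscale

    gray = to_grayscale(np.asarray(img, dtype=np.uint8))
    rgb = np.stack([gray, gray, gray], axis=2)
    edges = find_boundaries(np.asarray(mask), mode="outer")
    rgb[edges] = (255, 255, 0)
    iio.imwrite(Path(path), rgb)
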
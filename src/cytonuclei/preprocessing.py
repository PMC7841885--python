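"""Stage 1: grayscale conversion, smoothing and adaptive thresholding.

A nucleus is the darkest visible region within its cytoplasm, so the
foreground is the set of pixels strictly darker than their local window
mean minus an offset ``C`` (inverse-binary adaptive thresholding). The box
mean is computed with exact integer arithmetic so the strict inequality is
unambiguous at float precision.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["to_grayscale", "gaussian_blur", "adaptive_threshold"]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit raster to the grayscale working image.

    Three-channel (RGB) input yields the green channel verbatim — in stained
    cytology the green channel carries the most nuclear contrast.
    Single-channel input is returned unchanged.
    """
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got dtype {arr.dtype}")
    if arr.ndim == 2:
        return arr.copy()
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0].copy()
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr[:, :, 1].copy()
    raise ValueError(f"unsupported image shape {arr.shape}: need 1 or 3 channels")


def _gaussian_kernel_1d(ksize: int) -> np.ndarray:
    """Normalised 1-D Gaussian with sigma derived from the kernel size."""
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize, dtype=np.float64) - (ksize - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_blur(img: np.ndarray, kernel: int) -> np.ndarray:
    """Separable Gaussian smoothing with reflect borders; ``kernel=1`` is a no-op."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("gaussian_blur expects a 2-D grayscale image")
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return img.copy()
    k = _gaussian_kernel_1d(kernel)
    out = img.astype(np.float64)
    out = ndimage.correlate1d(out, k, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k, axis=1, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _box_window_sums(img: np.ndarray, wsize: int) -> np.ndarray:
    """Exact integer sum over the wsize x wsize reflect-padded window at each pixel."""
    r = wsize // 2
    # edge-repeating reflection, matching scipy.ndimage's "reflect" mode
    # used by every other stage
    padded = np.pad(img.astype(np.int64), r, mode="symmetric")
    # 2-D summed-area table with a zero guard row/column.
    sat = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    np.cumsum(padded, axis=0, out=sat[1:, 1:])
    np.cumsum(sat[1:, 1:], axis=1, out=sat[1:, 1:])
    h, w = img.shape
    return (
        sat[wsize : wsize + h, wsize : wsize + w]
        - sat[:h, wsize : wsize + w]
        - sat[wsize : wsize + h, :w]
        + sat[:h, :w]
    )


def adaptive_threshold(
    img: np.ndarray, wsize: int, C: float, mean_type: str = "box"
) -> np.ndarray:
    """Foreground mask of pixels strictly darker than their local mean minus ``C``.

    Parameters
    ----------
    img:
        2-D 8-bit grayscale image.
    wsize:
        Odd window side length, ``3 <= wsize <= min(height, width)``.
    C:
        Offset subtracted from the local mean.
    mean_type:
        ``"box"`` for the plain arithmetic window mean (exact), or
        ``"gaussian"`` for a Gaussian-weighted mean.

    Returns
    -------
    Boolean mask, True where ``intensity < localmean - C``.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("adaptive_threshold expects a 2-D grayscale image")
    if wsize < 3 or wsize % 2 == 0:
        raise ValueError(f"wsize must be odd and >= 3, got {wsize}")
    if wsize > min(img.shape):
        raise ValueError(
            f"wsize {wsize} exceeds smallest image dimension {min(img.shape)}"
        )
    if mean_type == "box":
        sums = _box_window_sums(img, wsize)
        n = wsize * wsize
        # intensity < sum/n - C  <=>  intensity*n < sum - C*n (integer-exact
        # when C is integral; float C falls back to the float comparison).
        if float(C).is_integer():
            return img.astype(np.int64) * n < sums - int(C) * n
        return img.astype(np.float64) < sums / n - C
    if mean_type == "gaussian":
        k = _gaussian_kernel_1d(wsize)
        mean = ndimage.correlate1d(img.astype(np.float64), k, axis=0, mode="reflect")
        mean = ndimage.correlate1d(mean, k, axis=1, mode="reflect")
        return img.astype(np.float64) < mean - C
    raise ValueError(f"mean_type must be 'box' or 'gaussian', got {mean_type!r}")
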
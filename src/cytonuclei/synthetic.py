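"""Seeded synthetic cytology-like images with ground-truth instance masks.

Each image emulates the qualitative structure of a Pap-smear field of
view: a bright background, brighter-than-nucleus elliptical cytoplasm
patches, and dark, convex, elliptical nuclei — one per cell — plus
distractors that exercise the shape filters: thin rotated bars (low
inertia ratio), concave crescent blobs (low solidity), and sub-minimum
speckle dots. Distractors share the nucleus intensity band so that only
contour properties, not darkness, can reject them. Nuclei are placed
without mutual overlap (with a small separation margin) and fully inside
the image; the ground-truth mask labels exactly the nucleus pixels in
placement order. All randomness comes from one generator keyed by the
seed, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

__all__ = ["SyntheticSpec", "GenerationError", "generate"]


class GenerationError(RuntimeError):
    """Raised when nucleus placement fails after bounded retries."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of one synthetic image.

    Defaults model a desk-scale field of view: 256x256 pixels (half the
    linear size of the 512x512 challenge images, nucleus radii scaled
    accordingly), 2–10 cells, nucleus intensities 40–80 inside cytoplasm
    140–180 on a 230 background, with Gaussian speckle noise of standard
    deviation 5.
    """

    image_size: tuple[int, int] = (256, 256)
    n_nuclei: tuple[int, int] = (2, 10)
    nucleus_axes: tuple[float, float] = (5.0, 12.0)
    nucleus_intensity: tuple[int, int] = (40, 80)
    cytoplasm_intensity: tuple[int, int] = (140, 180)
    background_intensity: int = 230
    noise_sd: float = 5.0
    n_artifacts: int = 3
    n_speckles: int = 10
    rgb: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.nucleus_intensity[1]
            < self.cytoplasm_intensity[0]
            < self.background_intensity
        ):
            raise ValueError(
                "need nucleus intensities < cytoplasm intensities < background"
            )
        if self.n_nuclei[0] > self.n_nuclei[1] or self.n_nuclei[0] < 0:
            raise ValueError("invalid n_nuclei range")
        if self.nucleus_axes[0] > self.nucleus_axes[1] or self.nucleus_axes[0] < 2:
            raise ValueError("invalid nucleus_axes range (min semi-axis >= 2)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


_MARGIN = 3  # minimum pixel separation between nuclei (and distractors)


def _dilate(mask: np.ndarray, it: int = _MARGIN) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool), iterations=it)


def generate(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray, list[dict[str, Any]]]:
    """Generate one image, its instance label mask, and a per-nucleus manifest.

    Returns
    -------
    image:
        uint8 array, 2-D grayscale or (H, W, 3) RGB with the signal in the
        green channel.
    gt:
        int32 instance label mask; labels 1..K in placement order mark
        exactly the nucleus pixels; distractors are absent from it.
    manifest:
        One record per nucleus: label, centre, semi-axes, orientation,
        intensity and drawn axis ratio (minor/major).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    canvas = np.full((h, w), float(spec.background_intensity))
    gt = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)  # nuclei + margin; also blocks distractors
    manifest: list[dict[str, Any]] = []

    lo, hi = spec.n_nuclei
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo

    # cells: cytoplasm ellipse first, nucleus on top of it
    for label in range(1, n + 1):
        placed = False
        for _ in range(200):
            a = float(rng.uniform(*spec.nucleus_axes))
            b = float(rng.uniform(spec.nucleus_axes[0], a))
            angle = float(rng.uniform(0, np.pi))
            cyto_scale = float(rng.uniform(2.0, 2.8))
            margin = a + 2
            r = float(rng.uniform(margin, h - 1 - margin))
            c = float(rng.uniform(margin, w - 1 - margin))
            rr, cc = draw_ellipse(r, c, a, b, shape=(h, w), rotation=angle)
            if rr.size == 0 or occupied[rr, cc].any():
                continue
            nuc = np.zeros((h, w), dtype=bool)
            nuc[rr, cc] = True
            crr, ccc = draw_ellipse(
                r, c, a * cyto_scale, b * cyto_scale, shape=(h, w), rotation=angle
            )
            cyto_val = float(rng.uniform(*spec.cytoplasm_intensity))
            nuc_val = float(rng.uniform(*spec.nucleus_intensity))
            canvas[crr, ccc] = cyto_val
            canvas[nuc] = nuc_val
            gt[nuc] = label
            occupied |= _dilate(nuc)
            manifest.append(
                {
                    "label": label,
                    "center": (r, c),
                    "semi_axes": (a, b),
                    "rotation": angle,
                    "nucleus_intensity": nuc_val,
                    "cytoplasm_intensity": cyto_val,
                    "axis_ratio": b / a,
                    "area": int(nuc.sum()),
                }
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place nucleus {label} after 200 attempts"
            )

    # distractor artifacts: thin bars (low inertia) and crescents (low solidity)
    for i in range(spec.n_artifacts):
        val = float(rng.uniform(*spec.nucleus_intensity))
        for _ in range(100):
            r = int(rng.integers(20, h - 20))
            c = int(rng.integers(20, w - 20))
            art = np.zeros((h, w), dtype=bool)
            if i % 2 == 0:  # thin rotated bar, length ~30, thickness 2
                angle = float(rng.uniform(0, np.pi))
                dr, dc = 15 * np.sin(angle), 15 * np.cos(angle)
                for off in range(2):
                    rr, cc = draw_line(
                        int(np.clip(r - dr, 0, h - 1)), int(np.clip(c - dc + off, 0, w - 1)),
                        int(np.clip(r + dr, 0, h - 1)), int(np.clip(c + dc + off, 0, w - 1)),
                    )
                    art[rr, cc] = True
            else:  # crescent: ellipse minus a shifted copy
                a = float(rng.uniform(8, 12))
                rr, cc = draw_ellipse(r, c, a, a, shape=(h, w))
                art[rr, cc] = True
                rr, cc = draw_ellipse(r, c + a * 0.55, a, a, shape=(h, w))
                art[rr, cc] = False
            if not (_dilate(art) & occupied).any() and art.any():
                canvas[art] = val
                occupied |= _dilate(art)
                break

    # speckles: 1–2 px dark dots, below any sensible MinSize
    for _ in range(spec.n_speckles):
        val = float(rng.uniform(*spec.nucleus_intensity))
        for _ in range(50):
            r = int(rng.integers(2, h - 2))
            c = int(rng.integers(2, w - 2))
            dot = np.zeros((h, w), dtype=bool)
            dot[r, c] = True
            if bool(rng.integers(0, 2)):
                dot[r, c + 1] = True
            if not (_dilate(dot) & occupied).any():
                canvas[dot] = val
                occupied |= _dilate(dot)
                break

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    gray = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    if spec.rgb:
        image = np.empty((h, w, 3), dtype=np.uint8)
        # red/blue carry low-contrast versions; the green channel holds the signal
        image[:, :, 0] = np.clip(np.rint(0.3 * canvas + 150), 0, 255).astype(np.uint8)
        image[:, :, 1] = gray
        image[:, :, 2] = np.clip(np.rint(0.2 * canvas + 170), 0, 255).astype(np.uint8)
    else:
        image = gray
    return image, gt, manifest
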
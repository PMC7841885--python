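"""Stage 3: candidate-region extraction and contour-property filtering.

Candidate nuclei are the 8-connected components of the noise-subtracted
foreground mask (holes filled). Each is described by four properties —
size, solidity, inertia ratio and mean intensity — and rejected unless it
is compact (solidity >= MinSolid), not elongated (inertia ratio >=
MinInertia) and of plausible size (MinSize <= size <= MaxSize).

Solidity is contour area over convex-hull area, the hull area being the
number of pixel centres inside or on the convex hull of the region's
pixels. The inertia ratio is the minor/major axis-length ratio of the
region's equivalent ellipse, i.e. sqrt(lambda_min / lambda_max) of the 2x2
second-central-moment matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .params import ParameterSet

__all__ = [
    "Region",
    "ContourFeatures",
    "extract_regions",
    "boundary_pixels",
    "solidity",
    "inertia_ratio",
    "region_size",
    "compute_features",
    "filter_regions",
    "features_table",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class Region:
    """One candidate nucleus: a filled 8-connected pixel set with its border.

    ``pixels`` and ``boundary`` are (N, 2) integer arrays of (row, col)
    coordinates in raster order; ``boundary`` is the subset of ``pixels``
    with at least one 8-neighbour outside the region (the image border
    counts as outside).
    """

    label: int
    pixels: np.ndarray
    boundary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if self.pixels.shape[0] == 0:
            raise ValueError("a Region must contain at least one pixel")
        if self.boundary is None:
            self.boundary = boundary_pixels(self.pixels)
        else:
            self.boundary = np.asarray(self.boundary, dtype=np.int64).reshape(-1, 2)

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.pixels[:, 0], self.pixels[:, 1]] = True
        return mask


@dataclass(frozen=True)
class ContourFeatures:
    size: int
    area: int
    solidity: float
    inertia_ratio: float
    mean_intensity: float


def _local_mask(pixels: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Boolean mask over the region's bounding box plus its offset."""
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    mask[pixels[:, 0] - r0, pixels[:, 1] - c0] = True
    return mask, int(r0), int(c0)


def boundary_pixels(pixels: np.ndarray) -> np.ndarray:
    """Pixels of the set with an 8-neighbour outside it, in raster order."""
    pixels = np.asarray(pixels, dtype=np.int64).reshape(-1, 2)
    mask, r0, c0 = _local_mask(pixels)
    interior = ndimage.binary_erosion(mask, structure=_EIGHT, border_value=0)
    rows, cols = np.nonzero(mask & ~interior)
    return np.column_stack((rows + r0, cols + c0))


def extract_regions(mask: np.ndarray) -> list[Region]:
    """8-connected components of a boolean mask, holes filled.

    Labels are assigned 1..K in raster-scan order of each component's first
    pixel; an empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    labelled, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    flat = labelled.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    # reversed so earlier raster indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    regions: list[Region] = []
    slices = ndimage.find_objects(labelled)
    for new_label, old_idx in enumerate(order, start=1):
        old_label = int(old_idx) + 1
        sl = slices[old_label - 1]
        local = labelled[sl] == old_label
        filled = ndimage.binary_fill_holes(local, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
        # filling may reach into a component nested inside this one's hole;
        # hole pixels stay with this region only if globally background,
        # keeping regions pairwise disjoint
        filled &= local | (labelled[sl] == 0)
        rows, cols = np.nonzero(filled)
        pixels = np.column_stack((rows + sl[0].start, cols + sl[1].start))
        regions.append(Region(label=new_label, pixels=pixels))
    return regions


def _hull_pixel_count(pixels: np.ndarray) -> int:
    """Number of pixel centres inside or on the convex hull of ``pixels``.

    Degenerate point sets (single pixel, collinear pixels) have a hull that
    covers exactly the region's own pixels at pixel resolution.
    """
    pts = pixels.astype(np.float64)
    if pts.shape[0] < 3:
        return pts.shape[0]
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return pts.shape[0]
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    rr, cc = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    cand = np.column_stack((rr.ravel(), cc.ravel())).astype(np.float64)
    # hull.equations: A @ x + b <= 0 for interior points
    inside = np.all(
        cand @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9, axis=1
    )
    return int(inside.sum())


def solidity(region: Region | np.ndarray) -> float:
    """Contour area divided by convex-hull area, in (0, 1]."""
    pixels = region.pixels if isinstance(region, Region) else np.asarray(region)
    pixels = pixels.reshape(-1, 2)
    hull_area = _hull_pixel_count(pixels)
    return pixels.shape[0] / hull_area


def inertia_ratio(region: Region | np.ndarray) -> float:
    """Minor/major axis-length ratio of the region's equivalent ellipse.

    Computed as sqrt(lambda_min / lambda_max) of the second-central-moment
    matrix of the pixel coordinates; 1.0 by convention for regions of fewer
    than 2 pixels, 0.0 for perfectly collinear ones.
    """
    pixels = region.pixels if isinstance(region, Region) else np.asarray(region)
    pixels = pixels.reshape(-1, 2).astype(np.float64)
    if pixels.shape[0] < 2:
        return 1.0
    centered = pixels - pixels.mean(axis=0)
    cov = centered.T @ centered / pixels.shape[0]
    lmin, lmax = np.linalg.eigvalsh(cov)
    if lmax <= 0:
        return 1.0
    return float(np.sqrt(max(lmin, 0.0) / lmax))


def region_size(region: Region, measure: str = "boundary") -> int:
    """Contour size: boundary pixel count (default) or filled area."""
    if measure == "boundary":
        return int(region.boundary.shape[0])
    if measure == "area":
        return region.area
    raise ValueError(f"unknown size measure {measure!r}")


def compute_features(
    region: Region, img: np.ndarray, size_measure: str = "boundary"
) -> ContourFeatures:
    mean_int = float(img[region.pixels[:, 0], region.pixels[:, 1]].mean())
    return ContourFeatures(
        size=region_size(region, size_measure),
        area=region.area,
        solidity=solidity(region),
        inertia_ratio=inertia_ratio(region),
        mean_intensity=mean_int,
    )


def filter_regions(
    regions: Sequence[Region], img: np.ndarray, params: ParameterSet
) -> list[Region]:
    """Keep regions with plausible size, high solidity and high inertia ratio.

    A region survives iff ``MinSize <= size <= MaxSize`` and
    ``solidity >= MinSolid`` and ``inertia_ratio >= MinInertia``; input
    order is preserved.
    """
    kept: list[Region] = []
    for region in regions:
        size = region_size(region, params.size_measure)
        if not params.MinSize <= size <= params.MaxSize:
            continue
        if solidity(region) < params.MinSolid:
            continue
        if inertia_ratio(region) < params.MinInertia:
            continue
        kept.append(region)
    return kept


def features_table(
    regions: Iterable[Region], img: np.ndarray, size_measure: str = "boundary"
) -> pd.DataFrame:
    """Per-region feature table (for CSV export / auditing)."""
    rows = []
    for region in regions:
        f = compute_features(region, img, size_measure)
        rows.append(
            {
                "label": region.label,
                "size": f.size,
                "area": f.area,
                "solidity": f.solidity,
                "inertia_ratio": f.inertia_ratio,
                "mean_intensity": f.mean_intensity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["label", "size", "area", "solidity", "inertia_ratio", "mean_intensity"],
    )
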
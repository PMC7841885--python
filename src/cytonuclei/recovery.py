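"""Stage 4: iterative nucleus-size recovery by intensity-guided growth.

Edge subtraction in stage 2 shrinks true nuclei. Each surviving region is
therefore re-grown: neighbouring pixels whose intensity lies within
``Irange`` of the region's running mean intensity are admitted one by one
(FIFO over the 8-neighbourhood, seeded by the boundary pixels in raster
order), with the mean updated after every admission. Growth stops when

1. no admissible neighbour remains,
2. the contour size exceeds ``MaxSize``, or
3. the contour's solidity drops below ``recovery_solidity`` (0.75, a bit
   below the usual solidity of a valid nucleus, ~0.8),

the last two being guards against uncontrolled growth in low-contrast
images. Pixels already owned by another region are never admitted; with
regions processed in label order, the first claimer keeps contested
pixels, making the output deterministic.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .contours import Region, boundary_pixels
from .params import ParameterSet

__all__ = ["grow_region", "recover_all"]

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class _GrowthState:
    """Incremental region state: running mean, size and solidity.

    The convex hull is only recomputed when an admitted pixel falls outside
    the current hull; a pixel inside the hull raises the solidity (area up,
    hull unchanged) and so can never trigger the solidity stop by itself.
    """

    def __init__(self, region: Region, img: np.ndarray, size_measure: str):
        self.img = img
        self.size_measure = size_measure
        self.mask = region.to_mask(img.shape)
        self.points: list[tuple[int, int]] = [tuple(p) for p in region.pixels]
        vals = img[region.pixels[:, 0], region.pixels[:, 1]].astype(np.float64)
        self.intensity_sum = float(vals.sum())
        self.area = len(self.points)
        self._hull_planes: np.ndarray | None = None
        self._hull_count = 0
        self._recompute_hull()

    @property
    def mean(self) -> float:
        return self.intensity_sum / self.area

    def admit(self, r: int, c: int) -> None:
        self.mask[r, c] = True
        self.points.append((r, c))
        self.intensity_sum += float(self.img[r, c])
        self.area += 1
        if self._hull_planes is None or not self._inside_hull(r, c):
            self._recompute_hull()

    def _inside_hull(self, r: int, c: int) -> bool:
        planes = self._hull_planes
        assert planes is not None
        return bool(np.all(planes[:, 0] * r + planes[:, 1] * c + planes[:, 2] <= 1e-9))

    def _recompute_hull(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape[0] < 3:
            self._hull_planes = None
            self._hull_count = pts.shape[0]
            return
        try:
            hull = ConvexHull(pts)
        except QhullError:  # collinear
            self._hull_planes = None
            self._hull_count = pts.shape[0]
            return
        self._hull_planes = hull.equations
        arr = np.asarray(self.points, dtype=np.int64)
        r0, c0 = arr.min(axis=0)
        r1, c1 = arr.max(axis=0)
        rr, cc = np.meshgrid(
            np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
        )
        cand = np.column_stack((rr.ravel(), cc.ravel())).astype(np.float64)
        inside = np.all(
            cand @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9, axis=1
        )
        self._hull_count = int(inside.sum())

    def solidity(self) -> float:
        return self.area / self._hull_count

    def size(self) -> int:
        if self.size_measure == "area":
            return self.area
        arr = np.asarray(self.points, dtype=np.int64)
        return int(boundary_pixels(arr).shape[0])


def grow_region(
    region: Region,
    img: np.ndarray,
    params: ParameterSet,
    claimed: np.ndarray | None = None,
) -> Region:
    """Grow one region on the raw grayscale image; returns a superset region.

    ``claimed`` marks pixels owned by other regions, which are never
    admitted. The input region is returned unchanged if a stopping
    condition already holds at entry.
    """
    img = np.asarray(img)
    state = _GrowthState(region, img, params.size_measure)
    if state.size() > params.MaxSize or state.solidity() < params.recovery_solidity:
        return Region(label=region.label, pixels=region.pixels.copy())

    h, w = img.shape
    queue: deque[tuple[int, int]] = deque(tuple(p) for p in region.boundary)
    stopped = False
    while queue and not stopped:
        pr, pc = queue.popleft()
        for dr, dc in _NEIGHBOURS:
            r, c = pr + dr, pc + dc
            if not (0 <= r < h and 0 <= c < w):
                continue
            if state.mask[r, c] or (claimed is not None and claimed[r, c]):
                continue
            if abs(float(img[r, c]) - state.mean) > params.Irange:
                continue
            state.admit(r, c)
            queue.append((r, c))
            if state.size() > params.MaxSize or state.solidity() < params.recovery_solidity:
                stopped = True
                break

    pixels = np.asarray(state.points, dtype=np.int64)
    order = np.lexsort((pixels[:, 1], pixels[:, 0]))
    return Region(label=region.label, pixels=pixels[order])


def recover_all(
    regions: Sequence[Region], img: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """Grow every region in label order and rasterise to an instance label mask.

    Input regions must be pairwise disjoint; grown regions stay disjoint
    because the pixels of every other region (grown or not yet processed)
    are off-limits during growth.
    """
    img = np.asarray(img)
    out = np.zeros(img.shape, dtype=np.int32)
    claimed = np.zeros(img.shape, dtype=bool)
    for region in regions:
        if claimed[region.pixels[:, 0], region.pixels[:, 1]].any():
            raise ValueError("input regions overlap; regions must be pairwise disjoint")
        claimed[region.pixels[:, 0], region.pixels[:, 1]] = True

    for region in sorted(regions, key=lambda r: r.label):
        claimed[region.pixels[:, 0], region.pixels[:, 1]] = False
        grown = grow_region(region, img, params, claimed=claimed)
        claimed[grown.pixels[:, 0], grown.pixels[:, 1]] = True
        out[grown.pixels[:, 0], grown.pixels[:, 1]] = region.label
    return out
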
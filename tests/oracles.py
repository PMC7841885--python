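"""Independent brute-force oracles used by the test suite.

Everything here is written as plainly as possible (explicit loops, python
sets) and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def reflect_index(i: int, n: int) -> int:
    """Reflect-101-free mirror indexing matching numpy's 'reflect' pad
    (symmetric: ... 2 1 0 | 0 1 2 ... n-1 | n-1 n-2 ...)."""
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        if i >= n:
            i = 2 * n - 1 - i
    return i


def box_threshold_bruteforce(img: np.ndarray, wsize: int, C: int) -> np.ndarray:
    """Per-pixel window mean by direct summation; foreground iff I < mean - C."""
    h, w = img.shape
    r = wsize // 2
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            total = 0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    total += int(img[reflect_index(i + di, h), reflect_index(j + dj, w)])
            # exact integer form of  I < total/w^2 - C
            out[i, j] = int(img[i, j]) * wsize * wsize < total - C * wsize * wsize
    return out


def kirsch_masks_literal() -> list[list[list[int]]]:
    """The eight compass kernels written out longhand."""
    return [
        [[5, 5, 5], [-3, 0, -3], [-3, -3, -3]],
        [[-3, 5, 5], [-3, 0, 5], [-3, -3, -3]],
        [[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]],
        [[-3, -3, -3], [-3, 0, 5], [-3, 5, 5]],
        [[-3, -3, -3], [-3, 0, -3], [5, 5, 5]],
        [[-3, -3, -3], [5, 0, -3], [5, 5, -3]],
        [[5, -3, -3], [5, 0, -3], [5, -3, -3]],
        [[5, 5, -3], [5, 0, -3], [-3, -3, -3]],
    ]


def kirsch_bruteforce(img: np.ndarray) -> np.ndarray:
    """Max over 8 directional *convolutions* (kernel flipped), clamped at 0
    before the max; reflect borders."""
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.int64)
    for mask in kirsch_masks_literal():
        for i in range(h):
            for j in range(w):
                acc = 0
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        # convolution: kernel index is negated offset
                        acc += mask[1 - di][1 - dj] * int(
                            img[reflect_index(i + di, h), reflect_index(j + dj, w)]
                        )
                if acc < 0:
                    acc = 0
                if acc > out[i, j]:
                    out[i, j] = acc
    return out


def flood_fill_8(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit flood fill, in raster order of
    first pixel."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def point_in_hull_by_volume(point, points) -> bool:
    """A point lies in the hull of ``points`` iff appending it leaves the
    hull area unchanged."""
    pts = np.asarray(points, dtype=float)
    try:
        base = ConvexHull(pts)
    except QhullError:
        return False
    aug = ConvexHull(np.vstack([pts, point]))
    return abs(aug.volume - base.volume) <= 1e-9


def solidity_bruteforce(pixels: np.ndarray) -> float:
    """Area over hull area via exhaustive pixel-in-hull enumeration."""
    pixels = np.asarray(pixels).reshape(-1, 2)
    pts = pixels.astype(float)
    try:
        ConvexHull(pts)
    except QhullError:
        return 1.0  # degenerate: hull covers exactly the region's pixels
    if pixels.shape[0] < 3:
        return 1.0
    r0, c0 = pixels.min(axis=0)
    r1, c1 = pixels.max(axis=0)
    count = 0
    for r in range(r0, r1 + 1):
        for c in range(c0, c1 + 1):
            if point_in_hull_by_volume((r, c), pts):
                count += 1
    return pixels.shape[0] / count


def inertia_ratio_bruteforce(pixels: np.ndarray) -> float:
    """Axis ratio from second central moments via the closed-form 2x2
    eigenvalues."""
    pixels = np.asarray(pixels).reshape(-1, 2)
    n = pixels.shape[0]
    if n < 2:
        return 1.0
    rbar = sum(p[0] for p in pixels) / n
    cbar = sum(p[1] for p in pixels) / n
    mu20 = sum((p[0] - rbar) ** 2 for p in pixels) / n
    mu02 = sum((p[1] - cbar) ** 2 for p in pixels) / n
    mu11 = sum((p[0] - rbar) * (p[1] - cbar) for p in pixels) / n
    tr, det = mu20 + mu02, mu20 * mu02 - mu11 * mu11
    disc = max(tr * tr / 4 - det, 0.0) ** 0.5
    lmax, lmin = tr / 2 + disc, tr / 2 - disc
    if lmax <= 0:
        return 1.0
    return (max(lmin, 0.0) / lmax) ** 0.5


def dice_sets(A, B) -> float:
    sa, sb = set(A), set(B)
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def aji_bruteforce(gt: np.ndarray, pred: np.ndarray) -> float:
    """AJI with python sets: per gt label (ascending), consume the unused
    prediction with the largest Jaccard (ties: lowest label)."""
    gt_sets = {int(k): set(zip(*np.nonzero(gt == k))) for k in np.unique(gt) if k > 0}
    pr_sets = {int(k): set(zip(*np.nonzero(pred == k))) for k in np.unique(pred) if k > 0}
    used = set()
    num = den = 0
    for g in sorted(gt_sets):
        G = gt_sets[g]
        best_p, best_j = None, -1.0
        for p in sorted(pr_sets):
            if p in used:
                continue
            P = pr_sets[p]
            inter = len(G & P)
            if inter == 0:
                continue
            j = inter / len(G | P)
            if j > best_j:
                best_p, best_j = p, j
        if best_p is None:
            den += len(G)
        else:
            used.add(best_p)
            num += len(G & pr_sets[best_p])
            den += len(G | pr_sets[best_p])
    for p in sorted(pr_sets):
        if p not in used:
            den += len(pr_sets[p])
    return num / den
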
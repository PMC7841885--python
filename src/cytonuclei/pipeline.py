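"""End-to-end orchestration of the four segmentation stages.

``segment_image`` composes the stages exactly as

    recover_all(
        filter_regions(
            extract_regions(
                subtract_edges(adaptive_threshold(blur(gray(img))),
                               edge_mask(kirsch_response(blur(gray(img)))))),
            gray(img), params),
        gray(img), params)

where the adaptive threshold and Kirsch filter see the *blurred* grayscale
image while contour mean intensities and recovery growth use the raw
grayscale. The result is a pure function of (pixels, parameters).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .contours import extract_regions, filter_regions
from .kirsch import edge_mask, kirsch_response, subtract_edges
from .params import ParameterSet
from .preprocessing import adaptive_threshold, gaussian_blur, to_grayscale
from .recovery import recover_all

__all__ = ["StageReport", "segment_image", "segment_batch"]

logger = logging.getLogger(__name__)


@dataclass
class StageReport:
    """Per-stage region counts, for auditing the filtering behaviour."""

    post_threshold: int = 0
    post_kirsch: int = 0
    post_filter: int = 0
    post_recovery: int = 0


def segment_image(
    img: np.ndarray, params: ParameterSet, report: StageReport | None = None
) -> np.ndarray:
    """Segment nuclei in one image; returns an int32 instance label mask."""
    gray = to_grayscale(np.asarray(img))
    blurred = gaussian_blur(gray, params.blur_kernel)

    fg = adaptive_threshold(blurred, params.wsize, params.C, params.mean_type)
    grad = kirsch_response(blurred)
    edges = edge_mask(grad, params.kirsch_edge_threshold)
    cleaned = subtract_edges(fg, edges)

    regions = extract_regions(cleaned)
    kept = filter_regions(regions, gray, params)
    # relabel survivors contiguously so output labels are 1..K
    from .contours import Region

    kept = [Region(label=i, pixels=r.pixels, boundary=r.boundary)
            for i, r in enumerate(kept, start=1)]
    mask = recover_all(kept, gray, params)

    if report is not None:
        from scipy import ndimage

        report.post_threshold = int(ndimage.label(fg, np.ones((3, 3)))[1])
        report.post_kirsch = len(regions)
        report.post_filter = len(kept)
        report.post_recovery = int(len(np.unique(mask)) - (1 if (mask == 0).any() else 0))
    logger.debug("segmented image: %d instances", int(mask.max()))
    return mask


def segment_batch(
    paths: Sequence[str | Path],
    params: ParameterSet,
    out_dir: str | Path,
    overlay: bool = False,
) -> pd.DataFrame:
    """Segment each input file, writing a 16-bit label mask per image.

    Failures on individual images are recorded in the returned report and
    the batch continues. Report columns: input, mask, n_instances,
    seconds, error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for path in paths:
        path = Path(path)
        row: dict = {"input": str(path), "mask": "", "n_instances": 0,
                     "seconds": 0.0, "error": ""}
        t0 = time.perf_counter()
        try:
            img = _io.read_image(path)
            mask = segment_image(img, params)
            mask_path = out_dir / f"{path.stem}_mask.png"
            _io.write_mask(mask_path, mask)
            row["mask"] = str(mask_path)
            row["n_instances"] = int(mask.max())
            if overlay:
                _io.write_overlay(out_dir / f"{path.stem}_overlay.png", img, mask)
        except Exception as exc:  # noqa: BLE001 — batch keeps going
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("failed on %s: %s", path, row["error"])
        row["seconds"] = round(time.perf_counter() - t0, 4)
        rows.append(row)
    return pd.DataFrame(rows, columns=["input", "mask", "n_instances", "seconds", "error"])
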
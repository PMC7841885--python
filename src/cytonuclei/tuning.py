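"""Grid search over the seven tunable parameters.

The tuner runs the full pipeline for every combination in the Cartesian
product of the per-parameter candidate lists, scores each combination
with the pooled (micro-averaged) evaluation over the training pairs, and
returns the argmax. A small annotated training set (about 10 images) is
enough in practice; no validation split is used, so the selected values
can overfit a tiny or unrepresentative training set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import evaluate_set
from .params import ParameterSet
from .pipeline import segment_image

__all__ = ["ParameterGrid", "default_grid", "synthetic_study_grid", "grid_search"]

logger = logging.getLogger(__name__)

_GRID_KEYS = ("wsize", "C", "Irange", "MinSolid", "MinSize", "MaxSize", "MinInertia")
_METRICS = ("precision", "recall", "f1", "aji")


@dataclass(frozen=True)
class ParameterGrid:
    """Candidate values per tunable parameter; every combination is tried."""

    wsize: tuple[int, ...]
    C: tuple[int, ...]
    Irange: tuple[int, ...]
    MinSolid: tuple[float, ...]
    MinSize: tuple[int, ...]
    MaxSize: tuple[int, ...]
    MinInertia: tuple[float, ...]

    def __post_init__(self) -> None:
        for key in _GRID_KEYS:
            if len(getattr(self, key)) == 0:
                raise ValueError(f"empty candidate list for {key}")

    def __len__(self) -> int:
        n = 1
        for key in _GRID_KEYS:
            n *= len(getattr(self, key))
        return n

    def combinations(self):
        """Deterministic enumeration: itertools.product in canonical key order."""
        lists = [getattr(self, key) for key in _GRID_KEYS]
        for values in itertools.product(*lists):
            yield dict(zip(_GRID_KEYS, values))

    @classmethod
    def from_mapping(cls, mapping) -> "ParameterGrid":
        return cls(**{k: tuple(mapping[k]) for k in _GRID_KEYS})


def default_grid() -> ParameterGrid:
    """General-purpose grid bracketing the published parameter rows."""
    return ParameterGrid(
        wsize=(35, 41, 55),
        C=(40, 48, 50),
        Irange=(30, 40),
        MinSolid=(0.6, 0.8, 0.85),
        MinSize=(5, 20),
        MaxSize=(50, 70, 140),
        MinInertia=(0.2, 0.3, 0.4),
    )


def synthetic_study_grid() -> ParameterGrid:
    """Compact 16-combination grid of published values, used by the
    desk-scale synthetic end-to-end study."""
    return ParameterGrid(
        wsize=(35, 55),
        C=(40, 50),
        Irange=(30, 40),
        MinSolid=(0.8,),
        MinSize=(5, 20),
        MaxSize=(140,),
        MinInertia=(0.3,),
    )


def grid_search(
    train_images: Sequence[np.ndarray],
    train_gts: Sequence[np.ndarray],
    grid: ParameterGrid,
    metric: str = "f1",
    base_params: ParameterSet | None = None,
) -> tuple[ParameterSet, float, pd.DataFrame]:
    """Exhaustive search; returns (best parameters, best score, full table).

    Ties are broken by the earliest combination in the deterministic
    enumeration order; NaN scores never win. ``base_params`` supplies the
    non-gridded fields (blur kernel, edge threshold, fixed constants).
    """
    if len(train_images) == 0 or len(train_images) != len(train_gts):
        raise ValueError("need >= 1 training (image, ground truth) pair")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    if len(grid) == 0:
        raise ValueError("empty parameter grid")
    base = base_params if base_params is not None else ParameterSet()
    logger.info(
        "grid search over %d combinations on %d images (no validation split: "
        "selected values may overfit a small training set)",
        len(grid), len(train_images),
    )

    best_params: ParameterSet | None = None
    best_score = -np.inf
    rows = []
    for combo in grid.combinations():
        params = base.replace(**combo)
        preds = [segment_image(img, params) for img in train_images]
        pooled, _ = evaluate_set(train_gts, preds, params.dice_threshold)
        row = {**combo, **{m: getattr(pooled, m) for m in _METRICS}}
        rows.append(row)
        score = row[metric]
        if np.isfinite(score) and score > best_score:
            best_score = float(score)
            best_params = params
    table = pd.DataFrame(rows, columns=list(_GRID_KEYS) + list(_METRICS))
    if best_params is None:  # every combination scored NaN
        best_params = base.replace(**next(grid.combinations()))
        best_score = float("nan")
    return best_params, best_score, table
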
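"""Tunable parameters of the segmentation pipeline.

The seven tunable parameters (``wsize``, ``C``, ``Irange``, ``MinSolid``,
``MinSize``, ``MaxSize``, ``MinInertia``) control the four pipeline stages;
the remaining fields are fixed constants of the method (recovery solidity,
Dice gate) and implementation knobs (blur kernel, Kirsch edge threshold).
Field names mirror the configuration-file keys exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterSet",
    "ISBI_PARAMS",
    "BSMMU_CASE1",
    "BSMMU_CASE2",
    "BSMMU_CASE3",
    "load_parameters",
]


@dataclass(frozen=True)
class ParameterSet:
    """Complete parameterisation of one pipeline run.

    Parameters
    ----------
    wsize:
        Adaptive-threshold window side length in pixels; odd, >= 3. Larger
        windows suit images where nuclei are more zoomed in.
    C:
        Adaptive-threshold offset in intensity levels, subtracted from the
        local window mean. Larger values suit lower nucleus/cytoplasm
        contrast.
    Irange:
        Allowable difference between a candidate pixel's intensity and the
        running mean intensity of a region during nucleus recovery.
    MinSolid:
        Minimum solidity (region area / convex hull area) a contour must
        reach to be kept; values near 0.8 are typical for nuclei.
    MinSize, MaxSize:
        Inclusive bounds on contour size (see ``size_measure``).
    MinInertia:
        Minimum minor/major equivalent-ellipse axis ratio; rejects elongated
        artifacts.
    recovery_solidity:
        Fixed stopping solidity of the recovery stage (growth halts when the
        grown contour's solidity drops below it); 0.75 by construction.
    dice_threshold:
        Fixed Dice gate for counting a detection as a true positive; 0.6.
    kirsch_edge_threshold:
        Gradient magnitude at or above which a pixel is declared an edge.
    blur_kernel:
        Side length of the Gaussian smoothing kernel; odd; 1 disables
        smoothing.
    mean_type:
        Local-mean flavour for the adaptive threshold: ``"box"`` (plain
        arithmetic mean, exact integer arithmetic) or ``"gaussian"``
        (Gaussian-weighted mean).
    size_measure:
        What "contour size" counts: ``"boundary"`` (outer-border pixel
        count, the default) or ``"area"`` (filled pixel count).
    """

    wsize: int = 35
    C: int = 50
    Irange: int = 40
    MinSolid: float = 0.8
    MinSize: int = 5
    MaxSize: int = 50
    MinInertia: float = 0.3
    recovery_solidity: float = 0.75
    dice_threshold: float = 0.6
    kirsch_edge_threshold: float = 255.0
    blur_kernel: int = 5
    mean_type: str = "box"
    size_measure: str = "boundary"

    def __post_init__(self) -> None:
        if self.wsize < 3 or self.wsize % 2 == 0:
            raise ValueError(f"wsize must be odd and >= 3, got {self.wsize}")
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError(f"blur_kernel must be odd and >= 1, got {self.blur_kernel}")
        if not 0.0 < self.MinSolid <= 1.0:
            raise ValueError(f"MinSolid must lie in (0, 1], got {self.MinSolid}")
        if not 0.0 <= self.MinInertia <= 1.0:
            raise ValueError(f"MinInertia must lie in [0, 1], got {self.MinInertia}")
        if not 0 < self.MinSize < self.MaxSize:
            raise ValueError(
                f"need 0 < MinSize < MaxSize, got {self.MinSize}, {self.MaxSize}"
            )
        if self.Irange < 0:
            raise ValueError(f"Irange must be >= 0, got {self.Irange}")
        if not 0.0 < self.recovery_solidity < 1.0:
            raise ValueError(
                f"recovery_solidity must lie in (0, 1), got {self.recovery_solidity}"
            )
        if not 0.0 < self.dice_threshold <= 1.0:
            raise ValueError(
                f"dice_threshold must lie in (0, 1], got {self.dice_threshold}"
            )
        if self.kirsch_edge_threshold < 0:
            raise ValueError("kirsch_edge_threshold must be >= 0")
        if self.mean_type not in ("box", "gaussian"):
            raise ValueError(f"mean_type must be 'box' or 'gaussian', got {self.mean_type!r}")
        if self.size_measure not in ("boundary", "area"):
            raise ValueError(
                f"size_measure must be 'boundary' or 'area', got {self.size_measure!r}"
            )

    def replace(self, **changes: Any) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(mapping))


# Published parameter rows: the public challenge dataset and the three
# hospital-slide cases trading precision against recall / AJI.
ISBI_PARAMS = ParameterSet(
    wsize=55, C=40, Irange=30, MinSolid=0.8, MinSize=20, MaxSize=140, MinInertia=0.4
)
BSMMU_CASE1 = ParameterSet(
    wsize=35, C=50, Irange=40, MinSolid=0.8, MinSize=5, MaxSize=50, MinInertia=0.3
)
BSMMU_CASE2 = ParameterSet(
    wsize=41, C=48, Irange=40, MinSolid=0.6, MinSize=5, MaxSize=50, MinInertia=0.2
)
BSMMU_CASE3 = ParameterSet(
    wsize=35, C=50, Irange=40, MinSolid=0.8, MinSize=5, MaxSize=70, MinInertia=0.4
)


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"configuration file {path} does not hold a mapping")
    return ParameterSet.from_mapping(data)
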
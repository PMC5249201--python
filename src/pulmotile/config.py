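"""Run configuration: a flat YAML file with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .segmentation import SegmentationParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Validated knobs of a quantification run; CLI flags override these."""

    pixel_size_um: float = 0.454
    reduction_factor: int = 8
    tile_side_px: int = 2
    min_inclusion: float = 1.0
    threshold_class: int = 12
    calibration_cutoff: float = 0.01
    palette: str | None = None
    control_group: str = "control"
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.reduction_factor < 1 or self.tile_side_px < 1:
            raise ValueError("reduction_factor and tile_side_px must be >= 1")
        if not 0 < self.min_inclusion <= 1:
            raise ValueError("min_inclusion must be in (0, 1]")
        if not 1 <= self.threshold_class <= 20:
            raise ValueError("threshold_class must be in 1..20")
        if not 0 < self.calibration_cutoff < 1:
            raise ValueError("calibration_cutoff must be in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    seg_data = data.pop("segmentation", {}) or {}
    known = {f.name for f in fields(RunConfig)} - {"segmentation"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    seg_known = {f.name for f in fields(SegmentationParams)}
    seg_unknown = set(seg_data) - seg_known
    if seg_unknown:
        raise ValueError(f"unknown segmentation config keys: {sorted(seg_unknown)}")
    return RunConfig(segmentation=SegmentationParams(**seg_data), **data)
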
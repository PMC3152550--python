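"""Run configuration: a single serializable record of every knob of a run.

The config round-trips through YAML (write -> read -> identical), and the
pipeline embeds the exact config and seed into every report so any run can
be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .segment import SegmentationParams
from .synth import SceneParams

__all__ = ["RunConfig"]


def _tupleize(obj):
    if isinstance(obj, list):
        return tuple(_tupleize(v) for v in obj)
    return obj


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to rerun a screen end-to-end."""

    scenario: str = "primary-screen"
    seed: int = 0
    n_extracts: int = 42
    fields_per_well: int = 1
    # screening-plate imaging scale: few, well-spread cells per field so that
    # even strong LD increasers remain resolvable as individual spots
    scene: SceneParams = field(
        default_factory=lambda: SceneParams(
            field_shape=(320, 320), n_cells=6, cytoplasm_radius_px=60.0
        )
    )
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(cytoplasm_radius_px=60.0)
    )
    k: float = 1.0  # SD multiplier of the normal range
    sd_ddof: int = 0  # 0 = population SD, 1 = sample SD
    background: str = "median"
    histogram_cap: int = 80
    shuffle_layout: bool = True
    write_images: bool = False
    out_dir: str = "ldscreen_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scene = d.pop("scene", {})
        seg = d.pop("segmentation", {})
        scene = {k: _tupleize(v) for k, v in scene.items()}
        seg = {k: _tupleize(v) for k, v in seg.items()}
        return cls(scene=SceneParams(**scene), segmentation=SegmentationParams(**seg), **d)

    def to_yaml(self, path: Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
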
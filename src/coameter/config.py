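"""Pipeline configuration with the published parameters as defaults."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .diagnosis import CRITERIA
from .segmentation import HsvColor, HsvRange

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every tunable of the measurement/diagnosis pipeline in one place.

    Defaults encode the published operating point: red HSV ranges
    [0,43,46]-[10,255,255] and [156,43,46]-[180,255,255], 3x3 morphology
    (one erosion, one dilation) and 3x3 Gaussian smoothing, slope tolerance
    0.0256, and the 10 mm / 379 px scale calibration.
    """

    hsv_ranges: list[list[list[int]]] = field(
        default_factory=lambda: [
            [[0, 43, 46], [10, 255, 255]],
            [[156, 43, 46], [180, 255, 255]],
        ]
    )
    opening_iterations: int = 1
    gaussian: bool = True
    slope_abs_tol: float = 0.0256
    scale_mm: float = 10.0
    scale_px: int = 379
    criteria: list[str] = field(default_factory=lambda: list(CRITERIA))
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    @property
    def mm_per_px(self) -> float:
        return self.scale_mm / self.scale_px

    def ranges(self) -> tuple[HsvRange, ...]:
        return tuple(
            HsvRange(HsvColor(*lo), HsvColor(*up)).validate() for lo, up in self.hsv_ranges
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
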
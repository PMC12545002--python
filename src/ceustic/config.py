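"""Run-level configuration: every pipeline tunable in one serializable place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .discreteness import RuleConfig
from .errors import ValidationError
from .ticmap import TicConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables of the end-to-end pipeline, with their defaults.

    Serializable to/from a single YAML or JSON file; unknown keys are
    rejected so a typo cannot silently fall back to a default.
    """

    # TIC analysis
    smooth_window: int = 5
    threshold_frac: float = 0.05
    noise_floor: float = 1e-6
    gradient_from: str = "start_intensity"
    parameter: str = "mean_gradient_to_peak"
    # motion
    motion_reference_index: int | None = None
    motion_max_shift: int = 5
    motion_subpixel: bool = True
    # hot-region segmentation: the pipeline default is Otsu, which adapts
    # the hot threshold to the map histogram; a fixed percentile instead
    # pins the hot area at a fixed fraction of the ROI
    hot_threshold_method: str = "otsu"
    hot_percentile: float = 75.0
    min_area: int = 5
    # discreteness rule cutpoints
    satellite_max: int = 4
    dominant_min_2: float = 0.70
    numerous_min: int = 6
    dominant_max_4: float = 0.35
    # rendering
    colormap: str = "jet"
    normalization: tuple[float, float] = (0.0, 100.0)
    # reader statistics
    icc_form: str = "single"
    ci_method: str = "clopper-pearson"
    # randomness
    seed: int = 0

    def tic_config(self) -> TicConfig:
        return TicConfig(
            smooth_window=self.smooth_window,
            threshold_frac=self.threshold_frac,
            noise_floor=self.noise_floor,
            gradient_from=self.gradient_from,
        )

    def rule_config(self) -> RuleConfig:
        return RuleConfig(
            satellite_max=self.satellite_max,
            dominant_min_2=self.dominant_min_2,
            numerous_min=self.numerous_min,
            dominant_max_4=self.dominant_max_4,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["normalization"] = list(self.normalization)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "normalization" in d:
            d = dict(d)
            d["normalization"] = tuple(d["normalization"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
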
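"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .io import DEFAULT_PATTERN
from .separation import SeparationConfig


@dataclass(frozen=True)
class MaskingConfig:
    method: str = "local_median"
    k_sigma: float = 3.0
    bg_window_px: int = 101
    min_contrast: float = 0.04
    min_object_area_frac: float = 0.2


@dataclass(frozen=True)
class ViabilityConfig:
    mode: str = "adaptive"  # adaptive | fixed
    fixed_threshold: float = 0.30
    neighborhood_width_px: int = 10
    #: darkness band over which the dead/alive call is expected to be robust
    threshold_range: tuple[float, float] = (0.25, 0.40)


@dataclass(frozen=True)
class RunConfig:
    input_dir: str = "."
    out_dir: str = "results"
    pattern: str = DEFAULT_PATTERN
    seed: int = 0
    initial_n: int | None = None
    masking: MaskingConfig = MaskingConfig()
    separation: SeparationConfig = SeparationConfig()
    viability: ViabilityConfig = ViabilityConfig()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "masking" in d and isinstance(d["masking"], dict):
            d["masking"] = MaskingConfig(**d["masking"])
        if "separation" in d and isinstance(d["separation"], dict):
            d["separation"] = SeparationConfig(**d["separation"])
        if "viability" in d and isinstance(d["viability"], dict):
            v = dict(d["viability"])
            if "threshold_range" in v:
                v["threshold_range"] = tuple(v["threshold_range"])
            d["viability"] = ViabilityConfig(**v)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
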
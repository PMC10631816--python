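"""Validated pipeline configuration.

`PipelineConfig` collects every tunable of the simulate -> angiography ->
vessels -> thickness -> statistics chain in one JSON-serializable object
(pydantic models, so a JSON schema is available via
``PipelineConfig.json_schema()``).  Every pipeline run writes its resolved
configuration next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .geometry import PhantomGeometry

__all__ = ["PipelineConfig", "load_config"]


class GeometryConfig(BaseModel):
    n_depth: int = 256
    n_fast: int = 256
    n_slow: int = 64
    axial_pixel_um: float = 14.0
    lateral_pixel_um: float = 35.0
    n_repeats: int = 4

    def to_geometry(self) -> PhantomGeometry:
        return PhantomGeometry(**self.model_dump())


class SimulateConfig(BaseModel):
    thickness_um: float = 150.0
    vessel_fraction: float = Field(0.2, ge=0.0, le=0.9)
    decorrelation: float = Field(1.0, ge=0.0, le=1.0)
    noise_floor: float = Field(0.05, ge=0.0)
    ablation_grid_pitch_px: int | None = None
    n_patients: int = 25


class IbdvConfig(BaseModel):
    mode: str = "inter"
    lateral_window: int = 3
    # default slab starts below the deepest surface position so that air
    # (pure detection noise, hence fully decorrelated) never enters the
    # en-face average
    z_lo: int = 40
    z_hi: int = 100

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("inter", "intra"):
            raise ValueError("mode must be 'inter' or 'intra'")
        return v

    @field_validator("lateral_window")
    @classmethod
    def _win(cls, v):
        if v < 1 or v % 2 == 0:
            raise ValueError("lateral_window must be a positive odd integer")
        return v


class FrangiConfig(BaseModel):
    scales: list[float] = [1.0, 2.0, 3.0, 4.0]
    beta: float = 0.5
    c: float | None = None


class BinarizeConfig(BaseModel):
    method: str = "seeded"
    threshold: float | None = None

    @field_validator("method")
    @classmethod
    def _method(cls, v):
        if v not in ("otsu", "fixed", "seeded"):
            raise ValueError("method must be 'otsu', 'fixed' or 'seeded'")
        return v


class SegmentationConfig(BaseModel):
    method: str = "classical"
    probability_threshold: float = Field(0.6, gt=0.0, lt=1.0)
    smoothing_sigma: float = 1.0
    min_thickness_px: int = 3
    max_thickness_px: int = 60

    @field_validator("method")
    @classmethod
    def _method(cls, v):
        if v not in ("classical", "network"):
            raise ValueError("method must be 'classical' or 'network'")
        return v


class StatsConfig(BaseModel):
    test: str = "paired-t"
    baseline_mode: str = "baseline"
    holm: bool = False

    @field_validator("test")
    @classmethod
    def _test(cls, v):
        if v not in ("paired-t", "wilcoxon"):
            raise ValueError("test must be 'paired-t' or 'wilcoxon'")
        return v


class PipelineConfig(BaseModel):
    seed: int = 0
    geometry: GeometryConfig = GeometryConfig()
    simulate: SimulateConfig = SimulateConfig()
    ibdv: IbdvConfig = IbdvConfig()
    frangi: FrangiConfig = FrangiConfig()
    binarize: BinarizeConfig = BinarizeConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def json_schema(cls) -> dict:
        return cls.model_json_schema()

    def write(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a JSON config file (defaults if None) and apply overrides.

    Raises a validation error naming the offending keys on schema
    violations.
    """
    data = json.loads(Path(path).read_text()) if path else {}
    if overrides:
        data.update(overrides)
    return PipelineConfig.model_validate(data)
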
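"""Pipeline configuration: one JSON document, strict keys, lossless round-trip.

Every tunable of the analysis stages lives here with its default; unknown
keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from .extraction import ExtractionConfig
from .synthetic import MarkerStainModel, TissueModel
from .types import RigidTransform


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MarkerConfig(_Strict):
    name: str
    cellular_fraction: float = 0.5
    diffuse_in_necrosis: float = 0.0
    rim_intensity: float = 0.0
    dab_od: float = 1.2
    diffuse_in_tissue: float = 0.0

    def to_model(self) -> MarkerStainModel:
        return MarkerStainModel(
            marker_name=self.name,
            cellular_fraction=self.cellular_fraction,
            diffuse_in_necrosis=self.diffuse_in_necrosis,
            rim_intensity=self.rim_intensity,
            dab_od=self.dab_od,
            diffuse_in_tissue=self.diffuse_in_tissue,
        )


class TransformConfig(_Strict):
    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0

    def to_transform(self) -> RigidTransform:
        return RigidTransform(dx=self.dx, dy=self.dy, rotation=self.rotation)


class SimulateConfig(_Strict):
    tile_size: int = 1024
    necrosis_fraction: float = 0.25
    n_necrotic_foci: int = 1
    palisade_width: int = 12
    cell_density: float = 2.0
    hypocellular_factor: float = 0.1
    glass_fraction: float = 0.1
    od_noise_sigma: float = 0.05
    marker_a: MarkerConfig = Field(
        default_factory=lambda: MarkerConfig(
            name="IBA1", cellular_fraction=0.6, rim_intensity=0.5
        )
    )
    marker_b: MarkerConfig = Field(
        default_factory=lambda: MarkerConfig(
            name="CD163", cellular_fraction=0.15, diffuse_in_necrosis=0.6, rim_intensity=0.1
        )
    )
    transform: TransformConfig = Field(
        default_factory=lambda: TransformConfig(dx=7.0, dy=-3.0, rotation=1.0)
    )

    def to_tissue_model(self, seed: int) -> TissueModel:
        return TissueModel(
            tile_size=self.tile_size,
            necrosis_fraction=self.necrosis_fraction,
            n_necrotic_foci=self.n_necrotic_foci,
            palisade_width=self.palisade_width,
            cell_density=self.cell_density,
            hypocellular_factor=self.hypocellular_factor,
            glass_fraction=self.glass_fraction,
            od_noise_sigma=self.od_noise_sigma,
            rng_seed=seed,
        )


class ExtractConfig(_Strict):
    color_space: str = "lab"
    k: int | None = None
    k_range: tuple[int, int] = (2, 6)
    darkness_threshold: float = 0.75
    brown_hue_range: tuple[float, float] = (10.0, 50.0)
    brown_saturation_min: float = 0.15
    tissue_saturation_min: float = 0.05
    tissue_value_max: float = 0.88
    fit_max_pixels: int | None = 200_000

    def to_extraction_config(self, seed: int) -> ExtractionConfig:
        return ExtractionConfig(
            color_space=self.color_space,
            k=self.k,
            k_range=tuple(self.k_range),
            darkness_threshold=self.darkness_threshold,
            brown_hue_range=tuple(self.brown_hue_range),
            brown_saturation_min=self.brown_saturation_min,
            tissue_saturation_min=self.tissue_saturation_min,
            tissue_value_max=self.tissue_value_max,
            fit_max_pixels=self.fit_max_pixels,
            seed=seed,
        )


class HeatmapConfig(_Strict):
    patch_size: int = 16
    hotspot_quantile: float = 0.9


class FusionConfig(_Strict):
    high_threshold: float = 0.75
    rotation_range: float = 4.0


class PipelineConfig(_Strict):
    """Top-level configuration; one per-stage section plus I/O paths."""

    seed: int = 0
    simulate: SimulateConfig | None = Field(default_factory=SimulateConfig)
    input_a: str | None = None  # used instead of simulation when set
    input_b: str | None = None
    extract: ExtractConfig = Field(default_factory=ExtractConfig)
    heatmap: HeatmapConfig = Field(default_factory=HeatmapConfig)
    fusion: FusionConfig = Field(default_factory=FusionConfig)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.model_validate(json.loads(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_demo_config() -> PipelineConfig:
    """The shipped demo: a simulated 1024^2 adjacent-section pair with a
    necrotic core, cellular marker A vs. diffuse-in-necrosis marker B."""
    return PipelineConfig()
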
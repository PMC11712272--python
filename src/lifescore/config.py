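"""Run configuration: a schema-validated structured-text (YAML) config.

Unknown keys are rejected so a typo never silently falls back to a default.
All randomness in a run flows from the single ``seed``, split per stage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .curves import CurveSpec
from .synth import WorldConfig

# stable per-stage offsets for seed splitting
STAGE_SEEDS = {
    "world": 0,
    "species": 1,
    "regression": 2,
    "scalability_large": 3,
    "scalability_subcell": 4,
}


class WorldSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lat_min: float = -0.2
    lat_max: float = 0.2
    lon_min: float = 0.0
    lon_max: float = 0.4
    coarse_res: float = 4.0
    fine_factor: int = 4
    n_species: dict[str, int] = Field(
        default_factory=lambda: {
            "amphibian": 8, "reptile": 7, "bird": 8, "mammal": 7
        }
    )
    range_px_min: int = 8
    range_px_max: int = 200
    fraction_migratory: float = 0.2
    habitat_breadth: int = 2
    fraction_arable_tolerant: float = 0.15
    placement_rule: str = "gradient"
    agriculture_intensity: float = 0.7
    pasture_share: float = 0.3
    urban_fraction: float = 0.02
    relief_m: float = 1500.0
    endemism_gradient: bool = False


class SamplingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cells: int = 50
    n_runs: int = 10


class SimulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    size_min_km2: float | None = None   # default: native cell area
    size_max_km2: float | None = None   # default: half the region's AOH span
    n_sizes: int = 10
    reps: int = 100
    subcell_sides: list[float] = Field(
        default_factory=lambda: [0.05, 0.1, 0.2, 0.5, 1.0]
    )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    world: WorldSection = Field(default_factory=WorldSection)
    curves: list[str] = Field(
        default_factory=lambda: [
            "power:z=0.1", "power:z=0.25", "power:z=0.5",
            "power:z=1.0", "gompertz:a=5,b=6",
        ]
    )
    default_curve: str = "power:z=0.25"
    scenarios: list[str] = Field(
        default_factory=lambda: ["conversion_to_arable", "reversion_to_natural"]
    )
    sampling: SamplingSection = Field(default_factory=SamplingSection)
    simulation: SimulationSection = Field(default_factory=SimulationSection)

    def world_config(self) -> WorldConfig:
        return WorldConfig(seed=self.seed, **self.world.model_dump())

    def curve_specs(self) -> list[CurveSpec]:
        return [CurveSpec.parse(c) for c in self.curves]

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, STAGE_SEEDS[stage]])


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
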
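"""Run configuration: one structured, serializable object drives a whole run.

Defaults mirror the full-scale study design (15 km uncertainty cap, VIF
threshold 4, member-selection TSS 0.7 with a 10 % fallback quantile,
20 000 / 5 000 pseudo-absences per set for the global / regional tier,
CV threshold 0.5, richness threshold at the central value of the range);
:meth:`RunConfig.demo` provides a desk-scale configuration for examples and
smoke runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grids import GridSpec
from .sdm import EnsembleSettings
from .synthetic import VirtualSpeciesConfig

__all__ = ["ScenarioConfig", "RunConfig"]


@dataclass
class ScenarioConfig:
    """Synthetic-environment scenario: what world the virtual species live in."""

    n_climate: int = 3
    n_habitat: int = 2
    autocorr_range_cells: float = 3.0
    duplicate_pairs: int = 1
    use_bias: bool = True
    bias_strength: float = 1.0


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    world_grid: GridSpec = field(
        default_factory=lambda: GridSpec(0.0, 0.0, 0.25, 60, 60)
    )
    region_grid: GridSpec = field(
        default_factory=lambda: GridSpec(5.0, 5.0, 0.25, 30, 30)
    )
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    species: list[VirtualSpeciesConfig] = field(default_factory=list)
    global_settings: EnsembleSettings = field(
        default_factory=lambda: EnsembleSettings(n_pseudo_absences=20_000)
    )
    regional_settings: EnsembleSettings = field(
        default_factory=lambda: EnsembleSettings(n_pseudo_absences=5_000)
    )
    max_uncertainty_m: float = 15_000.0
    vif_threshold: float = 4.0
    cv_threshold: float = 0.5
    richness_threshold: float | None = None  # None -> central value of range
    ignorance_half_saturation: float = 1.0
    exclusion_points: list[tuple[float, float, float]] = field(default_factory=list)
    master_seed: int = 0
    output_dir: str = "runs/latest"

    def __post_init__(self) -> None:
        if not 0 < self.global_settings.train_fraction < 1:
            raise ValueError("train_fraction must be in (0,1)")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")
        if not 0 <= self.cv_threshold <= 1:
            raise ValueError("cv_threshold must be in [0,1]")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world_grid"] = dataclasses.asdict(self.world_grid)
        d["region_grid"] = dataclasses.asdict(self.region_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["world_grid"] = GridSpec(**d["world_grid"])
        d["region_grid"] = GridSpec(**d["region_grid"])
        d["scenario"] = ScenarioConfig(**d.get("scenario", {}))
        d["species"] = [
            sp if isinstance(sp, VirtualSpeciesConfig) else VirtualSpeciesConfig(**sp)
            for sp in d.get("species", [])
        ]
        for key in ("global_settings", "regional_settings"):
            if key in d and not isinstance(d[key], EnsembleSettings):
                s = dict(d[key])
                if "algorithms" in s:
                    s["algorithms"] = tuple(s["algorithms"])
                d[key] = EnsembleSettings(**s)
        if "exclusion_points" in d:
            d["exclusion_points"] = [tuple(p) for p in d["exclusion_points"]]
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- canned configurations ---------------------------------------------

    @classmethod
    def demo(cls, master_seed: int = 0, output_dir: str = "runs/demo") -> "RunConfig":
        """Two virtual species on a 40x40 world grid; runs in minutes."""
        desk = dict(
            algorithms=("glm_logistic", "fda"),
            n_pa_sets=3,
            n_cv_runs=2,
            min_presences=20,
            gbm_n_estimators=100,
        )
        return cls(
            world_grid=GridSpec(0.0, 0.0, 0.25, 40, 40),
            region_grid=GridSpec(2.5, 2.5, 0.25, 20, 20),
            scenario=ScenarioConfig(n_climate=3, n_habitat=2, duplicate_pairs=1),
            species=[
                VirtualSpeciesConfig(
                    species_name="virtualis_calidus",
                    linear_coefficients={"climate_01": 2.0, "climate_02": -1.0},
                    prevalence_target=0.15,
                    n_records=800,
                    bias_layer_name="bias",
                    family="Virtualidae",
                    seed=11,
                ),
                VirtualSpeciesConfig(
                    species_name="virtualis_urbanus",
                    linear_coefficients={"climate_01": 1.5, "habitat_01": 1.5},
                    prevalence_target=0.15,
                    n_records=800,
                    bias_layer_name="bias",
                    family="Virtualidae",
                    seed=12,
                ),
            ],
            global_settings=EnsembleSettings(n_pseudo_absences=600, **desk),
            regional_settings=EnsembleSettings(n_pseudo_absences=200, **desk),
            master_seed=master_seed,
            output_dir=output_dir,
        )
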
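"""End-to-end runner: simulate -> prepare -> fit -> zones -> uncertainty -> report.

Each stage is an importable function; :func:`run_pipeline` chains them into
an output directory of plain-text artifacts (ASCII rasters, CSV tables, a
YAML copy of the effective configuration, a JSON manifest).  Reruns with an
identical configuration reproduce every numeric output: all randomness flows
from the master seed through labelled child seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from ._seeds import child_seed
from .config import RunConfig
from .grids import RasterLayer, RasterStack, write_raster
from .hierarchy import SpeciesRunResult, run_species
from .occurrence import CERTAIN_PLUS_NA, prepare_species
from .synthetic import (
    generate_environment,
    sample_occurrences,
    true_suitability,
    write_occurrences,
)
from .uncertainty import ignorance_map, mess_layer, mess_proportion
from .zoning import classify_zones, mean_cv_map, stack_richness, zone_statistics

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "simulate_inputs", "run_pipeline", "build_report"]

_GLOBAL_METRICS_COLUMNS = ["species", "n", "TSS", "Sensitivity", "Specificity",
                           "Cut-off binary", "Mean CV"]
_REGIONAL_METRICS_COLUMNS = _GLOBAL_METRICS_COLUMNS + ["Range filling"]


@dataclass
class PipelineResult:
    """In-memory handle on everything a run produced."""

    config: RunConfig
    world_stack: RasterStack
    bias: RasterLayer | None
    occurrences: dict[str, pd.DataFrame]
    truths: dict[str, RasterLayer]
    species_results: dict[str, SpeciesRunResult]
    skipped: dict[str, str]
    regional_metrics: pd.DataFrame
    global_metrics: pd.DataFrame
    zone_map: object
    zone_stats: pd.DataFrame
    mess_prop: RasterLayer
    ignorance: object
    run_dir: Path


def simulate_inputs(
    config: RunConfig,
) -> tuple[RasterStack, RasterLayer | None, dict[str, RasterLayer], dict[str, pd.DataFrame]]:
    """Generate the synthetic world: predictor stack, bias layer, truths, records.

    Occurrence sampling seeds are derived from the master seed and each
    species' own seed label, so a different ``master_seed`` yields a fresh
    but fully reproducible dataset.
    """
    sc = config.scenario
    stack = generate_environment(
        config.world_grid,
        n_climate=sc.n_climate,
        n_habitat=sc.n_habitat,
        autocorr_range_cells=sc.autocorr_range_cells,
        duplicate_pairs=sc.duplicate_pairs,
        seed=child_seed(config.master_seed, "environment"),
    )
    bias = None
    if sc.use_bias:
        rng = np.random.default_rng(child_seed(config.master_seed, "bias"))
        from scipy import ndimage

        field = ndimage.gaussian_filter(
            rng.standard_normal(config.world_grid.shape),
            sigma=max(sc.autocorr_range_cells, 1.0),
            mode="reflect",
        )
        field = (field - field.mean()) / field.std()
        bias = RasterLayer(
            config.world_grid, "bias", special.expit(sc.bias_strength * field)
        )
    truths: dict[str, RasterLayer] = {}
    occurrences: dict[str, pd.DataFrame] = {}
    for sp in config.species:
        eff = dataclasses.replace(
            sp, seed=child_seed(config.master_seed, "occurrences", sp.species_name, sp.seed)
        )
        truth = true_suitability(stack, eff)
        truths[sp.species_name] = truth
        occurrences[sp.species_name] = sample_occurrences(
            truth, eff, bias if sp.bias_layer_name else None
        )
    return stack, bias, truths, occurrences


def run_pipeline(config: RunConfig, run_dir: str | Path | None = None) -> PipelineResult:
    """Execute the whole pipeline and write the run directory.

    Per-species failures (too few presences, degenerate fits) skip the
    species with a logged reason and the run continues; failures of shared
    stages abort with a stage-tagged error.
    """
    run_dir = Path(run_dir or config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")

    stack, bias, truths, occurrences = simulate_inputs(config)
    occ_dir = run_dir / "occurrences"
    occ_dir.mkdir(exist_ok=True)
    for name, rec in occurrences.items():
        write_occurrences(rec, occ_dir / f"{name}.csv")

    results: dict[str, SpeciesRunResult] = {}
    skipped: dict[str, str] = {}
    for sp in config.species:
        name = sp.species_name
        try:
            results[name] = run_species(
                occurrences[name],
                stack,
                config.region_grid,
                config.global_settings,
                config.regional_settings,
                config.master_seed,
                max_uncertainty_m=config.max_uncertainty_m,
                exclusion_points=config.exclusion_points,
                vif_threshold=config.vif_threshold,
            )
        except ValueError as err:
            logger.warning("skipping species %s: %s", name, err)
            skipped[name] = str(err)
    if not results:
        raise RuntimeError(
            f"[fit stage] no species could be modelled; reasons: {skipped}"
        )

    raster_dir = run_dir / "rasters"
    raster_dir.mkdir(exist_ok=True)
    for name, res in results.items():
        for tier, pred in [("global", res.global_prediction), ("regional", res.regional_prediction)]:
            for kind in ("suitability", "cv", "binary"):
                write_raster(getattr(pred, kind), raster_dir / f"{name}_{tier}_{kind}.asc")

    # -- zoning -------------------------------------------------------------
    regional_binaries = {n: r.regional_prediction.binary for n, r in results.items()}
    global_binaries = {
        n: r.global_prediction.binary.extract(config.region_grid) for n, r in results.items()
    }
    regional_richness = stack_richness(regional_binaries, tier="regional")
    global_richness = stack_richness(global_binaries, tier="global")
    cv_layers = {n: r.regional_prediction.cv for n, r in results.items()}
    mean_cv = mean_cv_map(cv_layers)
    zone_map = classify_zones(
        mean_cv,
        regional_richness,
        global_richness,
        cv_threshold=config.cv_threshold,
        richness_threshold=config.richness_threshold,
    )
    write_raster(
        RasterLayer(zone_map.grid, "zones", zone_map.codes.astype(float),
                    ~zone_map.valid),
        run_dir / "zones.asc",
    )
    zone_map.legend_table().to_csv(run_dir / "zone_legend.csv", index=False)

    # -- uncertainty --------------------------------------------------------
    region_stack = stack.extract(config.region_grid)
    mess_layers = {}
    for name, res in results.items():
        pr, pc = res.regional_occurrences.cell_arrays()
        sub = region_stack.select(res.regional_selection.retained)
        ref = pd.DataFrame(sub.table(pr, pc), columns=res.regional_selection.retained)
        mess_layers[name] = mess_layer(ref, sub, name=f"mess_{name}")
        write_raster(mess_layers[name], raster_dir / f"{name}_mess.asc")
    mess_prop = mess_proportion(mess_layers)
    write_raster(mess_prop, run_dir / "mess_proportion.asc")

    all_records = pd.concat(list(occurrences.values()), ignore_index=True)
    ign = ignorance_map(
        all_records, config.region_grid, half_saturation=config.ignorance_half_saturation
    )
    write_raster(ign.ignorance, run_dir / "ignorance.asc")

    zone_stats = zone_statistics(
        zone_map,
        {"mess": mess_prop, "ignorance": ign.rescaled, "cv": mean_cv},
    )
    zone_stats.to_csv(run_dir / "zone_statistics.csv", index=False)

    # -- metrics & provenance ----------------------------------------------
    regional_rows, global_rows, provenance = [], [], []
    for name, res in results.items():
        g = {"species": name, **res.global_prediction.metrics_row()}
        g.pop("Range filling", None)
        global_rows.append(g)
        regional_rows.append({"species": name, **res.regional_prediction.metrics_row()})
        provenance.append(res.global_occurrences.ledger_row())
        provenance.append(res.regional_occurrences.ledger_row())
    regional_metrics = pd.DataFrame(regional_rows, columns=_REGIONAL_METRICS_COLUMNS)
    global_metrics = pd.DataFrame(global_rows, columns=_GLOBAL_METRICS_COLUMNS)
    regional_metrics.to_csv(run_dir / "metrics_regional.csv", index=False)
    global_metrics.to_csv(run_dir / "metrics_global.csv", index=False)
    pd.DataFrame(provenance).to_csv(run_dir / "provenance.csv", index=False)

    manifest = {
        "master_seed": config.master_seed,
        "n_species_modelled": len(results),
        "skipped": skipped,
        "zone_fractions": zone_map.fractions(),
        "cv_threshold": zone_map.cv_threshold,
        "richness_threshold": zone_map.richness_threshold,
        "stages": ["simulate", "prepare", "fit", "zones", "uncertainty", "report"],
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        world_stack=stack,
        bias=bias,
        occurrences=occurrences,
        truths=truths,
        species_results=results,
        skipped=skipped,
        regional_metrics=regional_metrics,
        global_metrics=global_metrics,
        zone_map=zone_map,
        zone_stats=zone_stats,
        mess_prop=mess_prop,
        ignorance=ign,
        run_dir=run_dir,
    )


def build_report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Assemble the consolidated tables from a completed run directory."""
    run_dir = Path(run_dir)
    required = {
        "metrics_regional": run_dir / "metrics_regional.csv",
        "metrics_global": run_dir / "metrics_global.csv",
        "zone_statistics": run_dir / "zone_statistics.csv",
        "provenance": run_dir / "provenance.csv",
        "manifest": run_dir / "manifest.json",
    }
    missing = [k for k, p in required.items() if not p.exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run at {run_dir}: missing stage outputs {missing}"
        )
    tables = {k: pd.read_csv(p) for k, p in required.items() if p.suffix == ".csv"}
    manifest = json.loads(required["manifest"].read_text())
    fractions = pd.DataFrame(
        [{"zone": z, "fraction": f} for z, f in manifest["zone_fractions"].items()]
    )
    tables["zone_fractions"] = fractions
    summary_path = run_dir / "report_zone_fractions.csv"
    fractions.to_csv(summary_path, index=False)
    return tables
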
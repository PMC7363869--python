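"""Canned validation experiments against known-truth virtual species.

These are the package's standard self-checks: simulate a species whose
suitability surface is known exactly, run the modelling machinery, and
measure how well it recovers the truth.  Both the test suite and the
reproduction script run them; scenario constants are the study conditions
and are not meant to be tuned per run.

Scenario design notes (see docs/methods.md for the full rationale):

* the *specialist* has |beta| = 2 on each climate predictor and a calibrated
  prevalence of 0.05 — a rare, strong-signal invader whose niche is sharply
  delimited and learnable;
* the world is 64 x 64 cells so that 2 000 pseudo-absence cells plus ~500
  presence cells fit without replacement;
* for hierarchy experiments the habitat term is a pure constraint (negative
  quadratic: it can only reduce suitability below the climate-only level)
  and the study region is sited over climatically favorable terrain, because
  an invaded study region is by construction broadly climatically suitable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import child_seed
from .grids import GridSpec, RasterLayer
from .hierarchy import run_species
from .occurrence import CERTAIN_PLUS_NA, prepare_species
from .sdm import (
    EnsembleSettings,
    binarize_ensemble,
    fit_ensemble,
    sample_pseudo_absences,
)
from .synthetic import (
    VirtualSpeciesConfig,
    climatically_favorable_region,
    generate_environment,
    sample_occurrences,
    true_suitability,
)

__all__ = [
    "RecoveryOutcome",
    "HierarchyOutcome",
    "parameter_recovery_replicate",
    "hierarchy_replicate",
]

_WORLD = GridSpec(0.0, 0.0, 0.25, 64, 64)
#: the specialist responds to every climate axis with |beta| = 2
_RECOVERY_COEFS = {"climate_01": 2.0, "climate_02": 2.0, "climate_03": 2.0}
#: hierarchy species: two climate axes plus a habitat constraint
_CLIMATE_COEFS = {"climate_01": 2.0, "climate_02": 2.0}
_PREVALENCE = 0.05  # recovery specialist: rare, sharply delimited niche
_HIER_PREVALENCE = 0.1  # hierarchy species: common enough to model regionally
_N_RECORDS = 900
_FAST_ROSTER = ("glm_logistic", "fda")


@dataclass
class RecoveryOutcome:
    ensemble_tss: float
    jaccard_with_truth: float
    n_presences: int


@dataclass
class HierarchyOutcome:
    global_area_on_region: int
    regional_area: int
    regional_tss: float

    @property
    def regional_smaller(self) -> bool:
        return self.regional_area < self.global_area_on_region


def parameter_recovery_replicate(seed: int) -> RecoveryOutcome:
    """One seeded parameter-recovery run of the single-tier ensemble.

    A strong-signal climate specialist is simulated, its records filtered /
    cleaned / thinned, and a committee ensemble fit against 2 000 random
    pseudo-absences.  Returns the ensemble evaluation TSS and the Jaccard
    overlap between the recovered binary range and the truth surface
    binarized by the same TSS-maximizing rule (same presences and
    pseudo-absences), i.e. truth and estimate are compared under one
    binarization convention.
    """
    stack = generate_environment(
        _WORLD, n_climate=3, n_habitat=2, autocorr_range_cells=3.0,
        duplicate_pairs=0, seed=child_seed(seed, "recovery", "env"),
    )
    cfg = VirtualSpeciesConfig(
        "virtualis_fortis",
        dict(_RECOVERY_COEFS),
        prevalence_target=_PREVALENCE,
        n_records=_N_RECORDS,
        seed=child_seed(seed, "recovery", "occ"),
    )
    truth = true_suitability(stack, cfg)
    records = sample_occurrences(truth, cfg)
    occ = prepare_species(records, _WORLD, CERTAIN_PLUS_NA)
    climate = stack.select([n for n in stack.names if n.startswith("climate")])
    settings = EnsembleSettings(
        algorithms=_FAST_ROSTER, n_pa_sets=3, n_cv_runs=2,
        n_pseudo_absences=2000, min_presences=30,
    )
    pred = fit_ensemble(
        occ.presence_cells, climate, settings,
        master_seed=seed, species=cfg.species_name, tier="recovery",
    )
    region = RasterLayer(_WORLD, "r", np.ones(_WORLD.shape))
    pa = sample_pseudo_absences(
        region, 2000, occ.presence_cells,
        seed=child_seed(seed, "recovery", "truth-pa"),
    )
    truth_binary, *_ = binarize_ensemble(truth, occ.presence_cells, pa)
    tb = truth_binary.values == 1
    pb = pred.binary.values == 1
    union = (tb | pb).sum()
    jac = float((tb & pb).sum() / union) if union else float("nan")
    return RecoveryOutcome(
        ensemble_tss=float(pred.tss),
        jaccard_with_truth=jac,
        n_presences=pred.n_presences,
    )


def hierarchy_replicate(seed: int) -> HierarchyOutcome | None:
    """One seeded two-tier run of a habitat-constrained virtual species.

    The species' truth is the climate specialist multiplied down by a
    habitat constraint (negative quadratic term).  Returns the global
    (climate-only) binary area clipped to the region versus the regional
    binary area, or None when the replicate leaves too few regional
    presences to model (the pipeline's skip rule).
    """
    stack = generate_environment(
        _WORLD, n_climate=3, n_habitat=2, autocorr_range_cells=3.0,
        duplicate_pairs=1, seed=child_seed(seed, "hier", "env"),
    )
    region = climatically_favorable_region(stack, _CLIMATE_COEFS, size=32, step=8)
    cfg = VirtualSpeciesConfig(
        "virtualis_limitatus",
        dict(_CLIMATE_COEFS),
        quadratic_coefficients={"habitat_01": -2.0},
        prevalence_target=_HIER_PREVALENCE,
        n_records=1200,
        seed=child_seed(seed, "hier", "occ"),
    )
    truth = true_suitability(stack, cfg)
    records = sample_occurrences(truth, cfg)
    gs = EnsembleSettings(
        algorithms=_FAST_ROSTER, n_pa_sets=3, n_cv_runs=2,
        n_pseudo_absences=1500, min_presences=30,
    )
    rs = EnsembleSettings(
        algorithms=_FAST_ROSTER, n_pa_sets=3, n_cv_runs=2,
        n_pseudo_absences=400, min_presences=20,
    )
    try:
        res = run_species(records, stack, region, gs, rs, master_seed=seed)
    except ValueError:
        return None
    ga = int((res.global_prediction.binary.extract(region).values == 1).sum())
    ra = int((res.regional_prediction.binary.values == 1).sum())
    return HierarchyOutcome(
        global_area_on_region=ga,
        regional_area=ra,
        regional_tss=float(res.regional_prediction.tss),
    )
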
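"""Two-tier hierarchical run: global climate model weighting regional
pseudo-absences.

A habitat-constrained species is modelled first globally (climate only,
certain+NA records), the global suitability is projected onto the invaded
region, converted into pseudo-absence weights by the inverse-logistic
transform, and the regional model (all predictors, certain records) is fit.
"""

import numpy as np

from hiersdm import EnsembleSettings, GridSpec, VirtualSpeciesConfig, run_species
from hiersdm.sdm import pseudo_absence_weight
from hiersdm.synthetic import (
    climatically_favorable_region,
    generate_environment,
    sample_occurrences,
    true_suitability,
)

world = GridSpec(0.0, 0.0, 0.25, 64, 64)
stack = generate_environment(world, 3, 2, 3.0, duplicate_pairs=1, seed=1)
coefs = {"climate_01": 2.0, "climate_02": 2.0}
region = climatically_favorable_region(stack, coefs, size=32)
print(f"region sited at ({region.min_lon}, {region.min_lat}) — the most "
      f"climatically favorable 32x32 window (the invaded-area premise)")

species = VirtualSpeciesConfig(
    "virtualis_limitatus", coefs,
    quadratic_coefficients={"habitat_01": -2.0},  # habitat only constrains
    prevalence_target=0.1, n_records=1200, seed=2,
)
records = sample_occurrences(true_suitability(stack, species), species)

fast = dict(algorithms=("glm_logistic", "fda"), n_pa_sets=3, n_cv_runs=2)
res = run_species(
    records, stack, region,
    EnsembleSettings(n_pseudo_absences=1500, min_presences=30, **fast),
    EnsembleSettings(n_pseudo_absences=400, min_presences=20, **fast),
    master_seed=0,
)

proj = res.global_projection.valid_values
print(f"global suitability on region: mean {proj.mean():.2f}; the derived "
      f"pseudo-absence weights average {pseudo_absence_weight(proj).mean():.2f} "
      f"(low weight where the climate already fits)")
ga = int((res.global_prediction.binary.extract(region).values == 1).sum())
ra = int((res.regional_prediction.binary.values == 1).sum())
print(f"binary suitable area on the region: climate-only {ga} cells, "
      f"full-predictor regional {ra} cells")
print("the regional model is the more restrictive one: adding habitat "
      "information shrinks the climatically suitable envelope")
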
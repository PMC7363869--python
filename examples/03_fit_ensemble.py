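"""Fit a committee-averaging ensemble for one species and tier.

Fits glm/gam/fda members across pseudo-absence sets and cross-validation
runs, selects members by TSS, committee-averages their binarized maps, and
prints the metrics row (the per-species line of the performance tables).
"""

from hiersdm import EnsembleSettings, GridSpec, VirtualSpeciesConfig, fit_ensemble
from hiersdm.occurrence import CERTAIN_PLUS_NA, prepare_species
from hiersdm.synthetic import generate_environment, sample_occurrences, true_suitability

grid = GridSpec(0.0, 0.0, 0.25, 64, 64)
stack = generate_environment(grid, 3, 2, 3.0, seed=1)
species = VirtualSpeciesConfig(
    "virtualis_fortis",
    {"climate_01": 2.0, "climate_02": 2.0, "climate_03": 2.0},
    prevalence_target=0.05, n_records=900, seed=2,
)
records = sample_occurrences(true_suitability(stack, species), species)
occ = prepare_species(records, grid, CERTAIN_PLUS_NA)
climate = stack.select([n for n in stack.names if n.startswith("climate")])

settings = EnsembleSettings(
    algorithms=("glm_logistic", "gam_spline", "fda"),
    n_pa_sets=3, n_cv_runs=2, n_pseudo_absences=2000, min_presences=30,
)
pred = fit_ensemble(occ.presence_cells, climate, settings, master_seed=0,
                    species=species.species_name, tier="demo")

row = pred.metrics_row()
print(f"members kept: {pred.n_members_used} of {len(pred.member_tss)} "
      f"(TSS >= {settings.tss_min} rule)")
for key, val in row.items():
    print(f"  {key:15s} {val:.3f}" if isinstance(val, float) else f"  {key:15s} {val}")
print("TSS = sensitivity + specificity - 1 at the printed cut-off; "
      "Mean CV is the average committee disagreement; range filling is the "
      "share of the predicted range already holding records")
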
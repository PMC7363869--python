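# hiersdm

Hierarchical presence-only species distribution modelling for invasive
species, from occurrence table to priority-management map.

Invasive species break the core assumption of classical species distribution
models (SDMs): they are not at equilibrium with their environment, so absence
of records in the invaded range rarely means unsuitable habitat. `hiersdm`
implements the two-tier remedy used to map invasion hotspots at continental
scale, together with everything around it — occurrence cleaning, predictor
collinearity screening, committee-averaging ensembles, richness stacking,
a six-zone priority classification and uncertainty surfaces — as a tested,
reusable Python library. A virtual-species generator replaces live GBIF and
climate-layer downloads, so the whole pipeline runs and validates itself at
desk scale against known ground truth.

## The method

For each species:

1. **Global tier.** A climate-only ensemble is fit on the species' worldwide
   records (native + invaded ranges; the permissive *certain+NA* occurrence
   variant) against `N` random pseudo-absences, approximating the global
   climatic niche.
2. **Pseudo-absence weighting.** The global suitability `p = projG(x)`
   projected onto the invaded region converts each regional pseudo-absence
   into a weight by the inverse-logistic transform

   `w(x) = 1 / (1 + (p/(p−1))²)`,  with `w = 0` at `p = 1`,

   so `w(0) = 1` (climatically hostile → trust the absence), `w(0.5) = 0.5`,
   `w(1) = 0` (climatically ideal → the absence is uninformative).
3. **Regional tier.** A full-predictor (climate + habitat) ensemble is fit on
   the region's precise (*certain*) records against the weighted
   pseudo-absences.

Each ensemble fits a roster of classifiers (polynomial logistic GLM, spline
GAM, flexible discriminant analysis, gradient boosting, optional
maxent-style L1 logistic) across several pseudo-absence draws and repeated
stratified 70/30 splits. Members with evaluation TSS ≥ 0.7 (true skill
statistic, `TSS = sensitivity + specificity − 1`) are kept — falling back to
the top 10 % — and **committee-averaged**: each member's map is binarized at
its own TSS-optimal cutoff and the ensemble suitability is the per-cell
fraction of members voting "presence", with the per-cell coefficient of
variation as an agreement measure.

Across species, binary maps stack into richness surfaces, and each cell is
classified by a three-way tree on (mean CV, regional richness, global
richness) into zones **A** coldspot, **B** hotspot, **C** uncertain
coldspot, **D** uncertain climatic hotspot, **E** uncertain environmental
hotspot, **F** uncertain hotspot. Three diagnostics qualify the result:
MESS extrapolation surfaces, a half-ignorance sampling-effort index
`h/(n+h)`, and Bhattacharyya distances between variant runs.

## Worked example

Each script in `examples/` demonstrates one capability. The end-to-end demo
(`examples/05_zoning_and_uncertainty.py`, two virtual species on a 40×40
world grid) prints, among other tables:

```
regional (full-predictor) model performance:
          species   n   TSS  Sensitivity  Specificity  Cut-off binary  Mean CV  Range filling
virtualis_calidus 120 0.482        0.867        0.615            0.01    0.078          0.484
virtualis_urbanus  64 0.478        0.562        0.915            0.01    0.060          0.514

priority-management zone fractions (CV threshold 0.5, richness threshold 1):
  A coldspot                          82.8%
  B hotspot                           17.0%
  ...
```

`n` is the number of presence cells after cleaning and thinning; the cut-off
is the suitability level that maximized TSS when binarizing the committee
average; range filling is the share of the predicted range that already
holds records (a proxy for distance to equilibrium). Zone fractions always
sum to 1 over valid cells. The same run writes ASCII rasters (suitability,
CV, binary, MESS, ignorance, zones) and CSV tables (metrics per tier,
per-zone uncertainty statistics, provenance ledger) to the run directory,
and is bit-reproducible under a fixed master seed.

A thin CLI wraps the same functions:

```bash
hiersdm run --seed 1 --out runs/demo      # simulate → fit → zones → report
hiersdm simulate --seed 1 --out runs/sim  # synthetic inputs only
hiersdm report runs/demo                  # re-assemble consolidated tables
```

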
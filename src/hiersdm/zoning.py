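"""Multi-species stacking and the priority-management-area classification.

Stacked binary predictions give a per-cell potential invasive-species
richness (one count per tier).  Cells are then classified into six priority
zones by a three-way tree on (i) the all-species mean coefficient of
variation of the regional ensembles (prediction certainty), (ii) regional
predicted richness and (iii) global predicted richness:

======  =========  =================  ===============
zone    CV         regional richness  global richness
======  =========  =================  ===============
A       low        low                (any)    coldspot
B       low        high               (any)    hotspot
C       high       low                low      uncertain coldspot
D       high       low                high     uncertain climatic hotspot
E       high       high               low      uncertain environmental hotspot
F       high       high               high     uncertain hotspot
======  =========  =================  ===============

"High" means strictly greater than the threshold (CV 0.5; richness the
central value of the 0..n_species range, 7 for 15 species), so cells at
exactly the printed central values land in "low".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterLayer

__all__ = [
    "ZONE_CODES",
    "ZONE_LABELS",
    "RichnessMap",
    "ZoneMap",
    "stack_richness",
    "mean_cv_map",
    "classify_zones",
    "zone_statistics",
]

ZONE_CODES = {
    "A": 1,
    "B": 2,
    "C": 3,
    "D": 4,
    "E": 5,
    "F": 6,
}
ZONE_LABELS = {
    "A": "coldspot",
    "B": "hotspot",
    "C": "uncertain_coldspot",
    "D": "uncertain_climatic_hotspot",
    "E": "uncertain_environmental_hotspot",
    "F": "uncertain_hotspot",
}
_MASKED = 0


@dataclass
class RichnessMap:
    """Per-cell count of species predicted present, for one tier."""

    grid: GridSpec
    richness: RasterLayer
    tier: str
    n_species: int


@dataclass
class ZoneMap:
    """Priority-management zones A-F on a grid (code 0 = masked)."""

    grid: GridSpec
    codes: np.ndarray  # int array, 0 masked, 1..6 = A..F
    cv_threshold: float
    richness_threshold: float
    n_species: int
    legend: dict[str, str] = field(default_factory=lambda: dict(ZONE_LABELS))

    @property
    def valid(self) -> np.ndarray:
        return self.codes != _MASKED

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.codes == ZONE_CODES[zone]

    def fractions(self) -> dict[str, float]:
        """Fraction of valid cells in each zone; sums to 1."""
        n_valid = int(self.valid.sum())
        if n_valid == 0:
            return {z: float("nan") for z in ZONE_CODES}
        return {z: float(self.zone_mask(z).sum()) / n_valid for z in ZONE_CODES}

    def legend_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"code": code, "zone": z, "label": ZONE_LABELS[z]}
                for z, code in ZONE_CODES.items()
            ]
        )


def stack_richness(binaries: dict[str, RasterLayer], tier: str = "") -> RichnessMap:
    """Sum per-species binary maps into a richness count per cell.

    A cell is nodata only where every species is nodata; species without
    data at a cell contribute zero.
    """
    if not binaries:
        raise ValueError("no binary layers given")
    layers = list(binaries.values())
    grid = layers[0].grid
    total = np.zeros(grid.shape)
    any_valid = np.zeros(grid.shape, dtype=bool)
    for name, layer in binaries.items():
        if layer.grid != grid:
            raise ValueError(f"binary layer {name!r} is on a different grid")
        v = layer.valid
        bad = layer.values[v][~np.isin(layer.values[v], (0.0, 1.0))]
        if len(bad):
            raise ValueError(f"layer {name!r} is not binary (found {bad[:3]}...)")
        total[v] += layer.values[v]
        any_valid |= v
    vals = np.where(any_valid, total, np.nan)
    layer = RasterLayer(grid, f"richness_{tier}" if tier else "richness", vals, ~any_valid)
    return RichnessMap(grid=grid, richness=layer, tier=tier, n_species=len(binaries))


def mean_cv_map(cv_layers: dict[str, RasterLayer]) -> RasterLayer:
    """Per-cell mean of the species' CV layers over species with data."""
    if not cv_layers:
        raise ValueError("no CV layers given")
    layers = list(cv_layers.values())
    grid = layers[0].grid
    total = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape)
    for name, layer in cv_layers.items():
        if layer.grid != grid:
            raise ValueError(f"CV layer {name!r} is on a different grid")
        v = layer.valid
        total[v] += layer.values[v]
        cnt[v] += 1
    mask = cnt == 0
    with np.errstate(invalid="ignore"):
        mean = np.where(mask, np.nan, total / np.where(mask, 1, cnt))
    return RasterLayer(grid, "mean_cv", mean, mask)


def default_richness_threshold(n_species: int) -> float:
    """Central value of the 0..n_species richness range (7 for 15 species)."""
    return float(n_species // 2)


def classify_zones(
    mean_cv: RasterLayer,
    regional_richness: RichnessMap,
    global_richness: RichnessMap,
    cv_threshold: float = 0.5,
    richness_threshold: float | None = None,
) -> ZoneMap:
    """Apply the priority-management classification tree per cell.

    Certainty first (CV strictly above the threshold -> uncertain branch),
    then regional richness, then — on the uncertain branch only — global
    richness.  Cells invalid in any input map are masked.
    """
    grid = mean_cv.grid
    if regional_richness.grid != grid or global_richness.grid != grid:
        raise ValueError("zone inputs on different grids")
    n_species = regional_richness.n_species
    if richness_threshold is None:
        richness_threshold = default_richness_threshold(n_species)

    cv = mean_cv.values
    rr = regional_richness.richness.values
    gr = global_richness.richness.values
    valid = mean_cv.valid & regional_richness.richness.valid & global_richness.richness.valid

    uncertain = cv > cv_threshold
    r_high = rr > richness_threshold
    g_high = gr > richness_threshold

    codes = np.zeros(grid.shape, dtype=int)
    codes[valid & ~uncertain & ~r_high] = ZONE_CODES["A"]
    codes[valid & ~uncertain & r_high] = ZONE_CODES["B"]
    codes[valid & uncertain & ~r_high & ~g_high] = ZONE_CODES["C"]
    codes[valid & uncertain & ~r_high & g_high] = ZONE_CODES["D"]
    codes[valid & uncertain & r_high & ~g_high] = ZONE_CODES["E"]
    codes[valid & uncertain & r_high & g_high] = ZONE_CODES["F"]
    return ZoneMap(
        grid=grid,
        codes=codes,
        cv_threshold=cv_threshold,
        richness_threshold=float(richness_threshold),
        n_species=n_species,
    )


def zone_statistics(
    zone_map: ZoneMap, extra_layers: dict[str, RasterLayer]
) -> pd.DataFrame:
    """Per-zone summary table: cell fraction plus mean/min/max of each layer.

    Zones with no cells report zero count and NaN statistics (an absent zone
    is a legitimate outcome, not an error).
    """
    for name, layer in extra_layers.items():
        if layer.grid != zone_map.grid:
            raise ValueError(f"layer {name!r} is on a different grid")
    n_valid = int(zone_map.valid.sum())
    rows = []
    for zone, code in ZONE_CODES.items():
        sel = zone_map.codes == code
        row: dict = {
            "zone": zone,
            "label": ZONE_LABELS[zone],
            "n_cells": int(sel.sum()),
            "fraction": (float(sel.sum()) / n_valid) if n_valid else float("nan"),
        }
        for name, layer in extra_layers.items():
            vals = layer.values[sel & layer.valid]
            if len(vals):
                row[f"{name}_mean"] = float(vals.mean())
                row[f"{name}_min"] = float(vals.min())
                row[f"{name}_max"] = float(vals.max())
            else:
                row[f"{name}_mean"] = row[f"{name}_min"] = row[f"{name}_max"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
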
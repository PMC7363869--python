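"""Non-model uncertainty surfaces: extrapolation, sampling effort, divergence.

Three complementary diagnostics qualify the ensemble predictions:

* **MESS** (multivariate environmental similarity surface) — per cell, the
  minimum over predictors of a similarity score comparing the cell's value
  with the distribution of reference (training) values; negative values flag
  environmental extrapolation, where predictions rest on conditions the
  model never saw.
* **Half-ignorance index** — a [0,1] transform ``h / (n + h)`` of the
  per-cell record count ``n`` of a reference taxonomic group; 1 where no
  records exist, 0.5 at the half-saturation count ``h``.  It maps the
  spatial sampling bias of opportunistic occurrence data, separating
  apparently unsuitable cells from simply unvisited ones.
* **Bhattacharyya distance** — divergence between two suitability maps
  treated as spatial densities; used to compare dataset-variant runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterLayer, points_to_cells

logger = logging.getLogger(__name__)

__all__ = [
    "MessResult",
    "IgnoranceMap",
    "mess_similarity",
    "mess_layer",
    "mess_proportion",
    "ignorance_map",
    "bhattacharyya_distance",
]


def mess_similarity(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Single-variable MESS similarity of target values against a reference.

    With ``p`` the percentage of reference values strictly below the target
    value, and reference min/max ``mn``/``mx``::

        p = 0        -> (t - mn) / (mx - mn) * 100     (negative below mn)
        0 < p <= 50  -> 2 p
        50 < p < 100 -> 2 (100 - p)
        p = 100      -> (mx - t) / (mx - mn) * 100     (negative above mx)
    """
    ref = np.sort(np.asarray(reference, dtype=float))
    t = np.asarray(target, dtype=float)
    mn, mx = ref[0], ref[-1]
    if mx == mn:
        raise ValueError("degenerate reference: min == max")
    p = 100.0 * np.searchsorted(ref, t, side="left") / len(ref)
    sim = np.where(p <= 50, 2 * p, 2 * (100 - p))
    sim = np.where(p == 0, (t - mn) / (mx - mn) * 100.0, sim)
    sim = np.where(p == 100, (mx - t) / (mx - mn) * 100.0, sim)
    return sim


def mess_layer(
    reference_values: pd.DataFrame,
    target_stack,
    name: str = "mess",
) -> RasterLayer:
    """Per-cell MESS: minimum single-variable similarity over predictors.

    ``reference_values`` holds the training-condition predictor values (one
    column per variable, matched to stack layers by name).  Variables whose
    reference range is degenerate are skipped with a warning.
    """
    if len(reference_values) == 0:
        raise ValueError("empty reference set")
    shared = [n for n in reference_values.columns if n in target_stack]
    if not shared:
        raise ValueError(
            f"no shared variables between reference {list(reference_values.columns)} "
            f"and stack {target_stack.names}"
        )
    valid = target_stack.valid_mask()
    rows, cols = np.nonzero(valid)
    best: np.ndarray | None = None
    for var in shared:
        ref = reference_values[var].to_numpy(float)
        ref = ref[np.isfinite(ref)]
        if len(ref) == 0 or np.ptp(ref) == 0:
            logger.warning("MESS: skipping degenerate variable %r", var)
            continue
        sim = mess_similarity(ref, target_stack[var].values[rows, cols])
        best = sim if best is None else np.minimum(best, sim)
    if best is None:
        raise ValueError("all variables degenerate in the reference set")
    arr = np.full(target_stack.grid.shape, np.nan)
    arr[rows, cols] = best
    return RasterLayer(target_stack.grid, name, arr, ~valid)


@dataclass
class MessResult:
    """Per-species MESS layers and the stacked dissimilarity proportion."""

    per_species: dict[str, RasterLayer]
    proportion: RasterLayer


def mess_proportion(per_species: dict[str, RasterLayer]) -> RasterLayer:
    """Per-cell fraction of species whose MESS is negative (dissimilar)."""
    if not per_species:
        raise ValueError("no MESS layers given")
    layers = list(per_species.values())
    grid = layers[0].grid
    neg = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape)
    for layer in layers:
        if layer.grid != grid:
            raise ValueError("MESS layers on different grids")
        v = layer.valid
        neg[v] += (layer.values[v] < 0).astype(float)
        cnt[v] += 1
    mask = cnt == 0
    with np.errstate(invalid="ignore"):
        prop = np.where(mask, np.nan, neg / np.where(mask, 1, cnt))
    return RasterLayer(grid, "mess_proportion", prop, mask)


@dataclass
class IgnoranceMap:
    """Sampling-effort bias surface from reference-group record counts."""

    grid: GridSpec
    ignorance: RasterLayer  # raw half-ignorance h/(n+h) in (0, 1]
    rescaled: RasterLayer  # min-max rescaled to [0, 1] for cross-map tables
    reference_grouping: str
    half_saturation: float

    @property
    def values(self) -> np.ndarray:
        return self.ignorance.values


def ignorance_map(
    records: pd.DataFrame,
    grid: GridSpec,
    half_saturation: float = 1.0,
    group_column: str = "family",
    per_group: bool = False,
) -> IgnoranceMap | dict[str, IgnoranceMap]:
    """Half-ignorance index ``h / (n + h)`` of per-cell record counts.

    By default counts are pooled over all reference groups (total records
    per cell); ``per_group=True`` returns one map per group instead.  The
    index is 1 where no records fall, 0.5 at ``n = half_saturation``, and
    strictly decreases with the record count.
    """
    if half_saturation <= 0:
        raise ValueError("half_saturation must be > 0")
    if per_group:
        return {
            str(g): ignorance_map(sub, grid, half_saturation, group_column, False)
            for g, sub in records.groupby(group_column)
        }
    counts = np.zeros(grid.shape)
    if len(records):
        rows, cols = points_to_cells(
            grid, records["lon"].to_numpy(float), records["lat"].to_numpy(float)
        )
        inside = rows >= 0
        np.add.at(counts, (rows[inside], cols[inside]), 1.0)
    ign = half_saturation / (counts + half_saturation)
    raw = RasterLayer(grid, "ignorance", ign)
    lo, hi = ign.min(), ign.max()
    scaled = (ign - lo) / (hi - lo) if hi > lo else np.zeros_like(ign)
    return IgnoranceMap(
        grid=grid,
        ignorance=raw,
        rescaled=RasterLayer(grid, "ignorance_rescaled", scaled),
        reference_grouping=f"pooled:{group_column}",
        half_saturation=half_saturation,
    )


def bhattacharyya_distance(map_a: RasterLayer, map_b: RasterLayer) -> float:
    """Bhattacharyya distance between two maps viewed as spatial densities.

    Both maps are normalized to sum 1 over their shared valid cells; the
    distance is ``-ln sum sqrt(p q)``: 0 for identical maps, ``inf`` for
    disjoint support.
    """
    if map_a.grid != map_b.grid:
        raise ValueError("maps on different grids")
    shared = map_a.valid & map_b.valid
    a = map_a.values[shared]
    b = map_b.values[shared]
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("maps must be nonnegative")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("all-zero map has no density")
    bc = float(np.sqrt((a / sa) * (b / sb)).sum())
    if bc <= 0:
        return float("inf")
    return float(-np.log(min(bc, 1.0)))
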
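"""Occurrence filtering, coordinate cleaning and one-per-cell thinning.

Presence-only records pass three ordered stages before modelling:

1. **filter** — keep georeferenced human/machine observations whose
   coordinate uncertainty is at most 15 000 m (roughly the circumradius of a
   0.25 degree cell).  Two dataset variants differ only in how a missing
   uncertainty is treated: the *certain* variant drops it, the *certain+NA*
   variant keeps it.  The looser variant feeds the global climate tier (more
   geographic coverage), the stricter one the regional tier (more precision).
2. **clean** — remove the classic coordinate errors: (0,0) points, records
   with longitude exactly equal to latitude, exact duplicates, and records
   within a configurable radius of known problem points (country centroids,
   institution coordinates) supplied as an exclusion list.
3. **thin** — collapse to one presence per grid cell.

Each stage's record count is kept in a provenance ledger on the resulting
:class:`SpeciesOccurrenceSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, points_to_cells

__all__ = [
    "Variant",
    "SpeciesOccurrenceSet",
    "filter_records",
    "clean_coordinates",
    "thin_to_grid",
    "prepare_species",
]

CERTAIN = "certain"
CERTAIN_PLUS_NA = "certain_plus_NA"
Variant = str

_KEPT_BASES = {"human_observation", "machine_observation"}

#: metres per degree of latitude, for exclusion-radius tests
_M_PER_DEG = 111_320.0


@dataclass
class SpeciesOccurrenceSet:
    """Per-species presence cells plus the provenance ledger."""

    species: str
    variant: Variant
    grid: GridSpec
    presence_cells: set[tuple[int, int]]
    n_raw: int
    n_after_filters: int
    n_after_cleaning: int
    n_after_thinning: int = field(default=0)
    n_outside_extent: int = 0

    def __post_init__(self) -> None:
        self.n_after_thinning = len(self.presence_cells)
        counts = (
            self.n_raw,
            self.n_after_filters,
            self.n_after_cleaning,
        )
        if not (counts[0] >= counts[1] >= counts[2] >= self.n_after_thinning):
            raise ValueError(f"provenance counts not monotone: {counts}")

    @property
    def n_presences(self) -> int:
        return len(self.presence_cells)

    def cell_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (rows, cols) arrays of the presence cells."""
        cells = sorted(self.presence_cells)
        if not cells:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.array(cells, dtype=int)
        return arr[:, 0], arr[:, 1]

    def ledger_row(self) -> dict:
        return {
            "species": self.species,
            "variant": self.variant,
            "n_raw": self.n_raw,
            "n_after_filters": self.n_after_filters,
            "n_after_cleaning": self.n_after_cleaning,
            "n_after_thinning": self.n_after_thinning,
            "n_outside_extent": self.n_outside_extent,
        }


def filter_records(
    records: pd.DataFrame,
    variant: Variant,
    max_uncertainty_m: float = 15_000.0,
) -> pd.DataFrame:
    """Keep georeferenced human/machine observations within the precision cap.

    The cap is inclusive (a record at exactly ``max_uncertainty_m`` is kept).
    Under ``certain`` a missing uncertainty drops the record; under
    ``certain_plus_NA`` it is kept.  Record order is preserved.
    """
    if variant not in (CERTAIN, CERTAIN_PLUS_NA):
        raise ValueError(f"unknown variant {variant!r}")
    geo = np.isfinite(records["lon"]) & np.isfinite(records["lat"])
    basis_ok = records["basis_of_record"].isin(_KEPT_BASES)
    unc = records["coordinate_uncertainty_m"]
    precise = unc <= max_uncertainty_m
    if variant == CERTAIN_PLUS_NA:
        precise = precise | unc.isna()
    return records[geo & basis_ok & precise]


def clean_coordinates(
    records: pd.DataFrame,
    exclusion_points: list[tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Remove common coordinate errors.

    Drops (0,0) records, records with lon == lat exactly, exact duplicates
    (same species/lon/lat; the first survives), and records within
    ``radius_m`` of any ``(lon, lat, radius_m)`` exclusion point (the
    configurable stand-in for country-centroid / institution gazetteers).
    """
    lon = records["lon"].to_numpy(float)
    lat = records["lat"].to_numpy(float)
    bad = ((lon == 0.0) & (lat == 0.0)) | (lon == lat)
    bad |= records.duplicated(subset=["species", "lon", "lat"]).to_numpy()
    for ex_lon, ex_lat, radius_m in exclusion_points or []:
        # equirectangular distance; adequate at gazetteer radii (< ~100 km)
        dx = (lon - ex_lon) * np.cos(np.deg2rad(ex_lat)) * _M_PER_DEG
        dy = (lat - ex_lat) * _M_PER_DEG
        bad |= dx * dx + dy * dy <= radius_m * radius_m
    return records[~bad]


def thin_to_grid(records: pd.DataFrame, grid: GridSpec) -> SpeciesOccurrenceSet:
    """Collapse cleaned records to one presence per grid cell.

    Records outside the grid extent are dropped and counted in the ledger.
    Raw/filter counts in the returned set equal the input count; use
    :func:`prepare_species` for the full three-stage ledger.
    """
    species = str(records["species"].iloc[0]) if len(records) else ""
    rows, cols = points_to_cells(
        grid, records["lon"].to_numpy(float), records["lat"].to_numpy(float)
    )
    inside = rows >= 0
    cells = set(zip(rows[inside].tolist(), cols[inside].tolist()))
    n = len(records)
    return SpeciesOccurrenceSet(
        species=species,
        variant=CERTAIN,
        grid=grid,
        presence_cells=cells,
        n_raw=n,
        n_after_filters=n,
        n_after_cleaning=n,
        n_outside_extent=int(n - inside.sum()),
    )


def prepare_species(
    records: pd.DataFrame,
    grid: GridSpec,
    variant: Variant,
    max_uncertainty_m: float = 15_000.0,
    exclusion_points: list[tuple[float, float, float]] | None = None,
) -> SpeciesOccurrenceSet:
    """Run filter -> clean -> thin and assemble the provenance ledger."""
    species = str(records["species"].iloc[0]) if len(records) else ""
    filtered = filter_records(records, variant, max_uncertainty_m)
    cleaned = clean_coordinates(filtered, exclusion_points)
    thinned = thin_to_grid(cleaned, grid) if len(cleaned) else None
    return SpeciesOccurrenceSet(
        species=species,
        variant=variant,
        grid=grid,
        presence_cells=thinned.presence_cells if thinned else set(),
        n_raw=len(records),
        n_after_filters=len(filtered),
        n_after_cleaning=len(cleaned),
        n_outside_extent=thinned.n_outside_extent if thinned else 0,
    )
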
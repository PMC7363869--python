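"""Virtual species: known-truth environments and GBIF-like occurrence tables.

Real applications of the pipeline start from GBIF occurrence downloads and
gridded climate/land-use layers.  This module replaces both with synthetic
counterparts generated from a known ground-truth suitability surface, so that
every downstream stage — filtering, thinning, collinearity removal, the
two-tier ensemble, zoning, uncertainty maps — can be exercised and validated
at desk scale, including parameter-recovery tests against the truth.

The generator emulates the awkward parts of real presence-only data:

* spatially autocorrelated, partially collinear predictors;
* opportunistic sampling biased by an effort layer;
* a coordinate-uncertainty column that is log-normally distributed and
  missing for a configurable fraction of records (the *certain* vs
  *certain+NA* dataset distinction);
* the three classic coordinate errors the cleaning stage removes: zero
  coordinates, longitude==latitude, and exact duplicates.

Injected errors are labelled in a ``raw_flags`` column that the pipeline
never reads; only tests do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .grids import GridSpec, RasterLayer, RasterStack

__all__ = [
    "VirtualSpeciesConfig",
    "OCCURRENCE_COLUMNS",
    "generate_environment",
    "true_suitability",
    "sample_occurrences",
    "write_occurrences",
    "read_occurrences",
]

#: Internal occurrence-table columns (Darwin-Core-like names used on disk).
OCCURRENCE_COLUMNS = [
    "species",
    "lon",
    "lat",
    "coordinate_uncertainty_m",
    "basis_of_record",
    "family",
    "raw_flags",
]

_DWC_RENAME = {
    "lon": "decimalLongitude",
    "lat": "decimalLatitude",
    "coordinate_uncertainty_m": "coordinateUncertaintyInMeters",
    "basis_of_record": "basisOfRecord",
}


@dataclass
class VirtualSpeciesConfig:
    """Ground-truth definition of one virtual species.

    Suitability is ``logistic(intercept + sum b_i x_i + sum g_i x_i^2)`` over
    named predictor layers.  When ``prevalence_target`` is set the intercept
    is re-solved so mean suitability over valid cells hits the target.

    Uncertainty defaults (log-mean ``log 5000`` m, log-sd 1) put a nontrivial
    fraction of records on either side of the 15 km precision filter.
    """

    species_name: str
    linear_coefficients: dict[str, float]
    quadratic_coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    prevalence_target: float | None = None
    n_records: int = 500
    bias_layer_name: str | None = None
    p_missing_uncertainty: float = 0.2
    uncertainty_log_mean: float = float(np.log(5000.0))
    uncertainty_log_sd: float = 1.0
    p_error_records: float = 0.05
    family: str = "Synthetidae"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [
            ("p_missing_uncertainty", self.p_missing_uncertainty),
            ("p_error_records", self.p_error_records),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        coefs = list(self.linear_coefficients.values()) + list(
            self.quadratic_coefficients.values()
        )
        if not any(c != 0 for c in coefs):
            raise ValueError("at least one coefficient must be nonzero")
        if self.prevalence_target is not None and not (
            0.0 < self.prevalence_target < 1.0
        ):
            raise ValueError("prevalence_target must be in (0,1)")


def _smoothed_field(
    rng: np.random.Generator, shape: tuple[int, int], range_cells: float
) -> np.ndarray:
    """Standardized Gaussian random field with the given correlation range."""
    z = rng.standard_normal(shape)
    if range_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=range_cells, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    if sd < 1e-15:
        raise ValueError("degenerate field: grid too small for requested smoothing")
    return z / sd


def generate_environment(
    grid: GridSpec,
    n_climate: int = 3,
    n_habitat: int = 2,
    autocorr_range_cells: float = 3.0,
    duplicate_pairs: int = 0,
    seed: int = 0,
) -> RasterStack:
    """Generate a predictor stack of smoothed, standardized random fields.

    Layers are named ``climate_01..`` and ``habitat_01..``; the name prefix is
    the tier tag used by predictor selection.  ``duplicate_pairs`` extra
    layers are near-copies (|r| > 0.99) of existing layers, named
    ``<source>_dup``, so that stepwise VIF removal has planted collinearity
    to find.
    """
    if n_climate < 1 or n_habitat < 0:
        raise ValueError("need at least one climate layer and n_habitat >= 0")
    if autocorr_range_cells < 0:
        raise ValueError("autocorr_range_cells must be >= 0")
    if autocorr_range_cells > 0 and min(grid.n_rows, grid.n_cols) < 4 * autocorr_range_cells:
        raise ValueError(
            f"grid {grid.shape} too small for smoothing range {autocorr_range_cells}"
        )
    rng = np.random.default_rng(seed)
    layers: list[RasterLayer] = []
    for i in range(n_climate):
        layers.append(
            RasterLayer(
                grid,
                f"climate_{i + 1:02d}",
                _smoothed_field(rng, grid.shape, autocorr_range_cells),
            )
        )
    for i in range(n_habitat):
        layers.append(
            RasterLayer(
                grid,
                f"habitat_{i + 1:02d}",
                _smoothed_field(rng, grid.shape, autocorr_range_cells),
            )
        )
    n_base = len(layers)
    for j in range(duplicate_pairs):
        src = layers[j % n_base]
        # tiny independent noise keeps |r| > 0.99 while avoiding exact ties
        noisy = src.values + 0.01 * rng.standard_normal(grid.shape)
        noisy = (noisy - noisy.mean()) / noisy.std()
        layers.append(RasterLayer(grid, f"{src.name}_dup", noisy))
    return RasterStack(grid, layers)


def _linear_predictor(stack: RasterStack, cfg: VirtualSpeciesConfig) -> np.ndarray:
    eta = np.zeros(stack.grid.shape)
    for name, beta in cfg.linear_coefficients.items():
        if name not in stack:
            raise KeyError(f"predictor {name!r} not in stack {stack.names}")
        eta += beta * stack[name].values
    for name, gamma in cfg.quadratic_coefficients.items():
        if name not in stack:
            raise KeyError(f"predictor {name!r} not in stack {stack.names}")
        eta += gamma * stack[name].values ** 2
    return eta


def true_suitability(stack: RasterStack, cfg: VirtualSpeciesConfig) -> RasterLayer:
    """Ground-truth suitability surface in (0, 1).

    If ``prevalence_target`` is set, the intercept is re-solved by bisection
    so the mean suitability over valid cells matches the target within 0.005.
    """
    eta = _linear_predictor(stack, cfg)
    valid = stack.valid_mask()
    intercept = cfg.intercept
    if cfg.prevalence_target is not None:
        lo, hi = -50.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            prev = special.expit(mid + eta[valid]).mean()
            if abs(prev - cfg.prevalence_target) < 1e-4:
                break
            if prev < cfg.prevalence_target:
                lo = mid
            else:
                hi = mid
        intercept = mid
    suit = special.expit(intercept + eta)
    suit = np.where(valid, suit, np.nan)
    return RasterLayer(stack.grid, f"truth_{cfg.species_name}", suit, ~valid)


def sample_occurrences(
    truth: RasterLayer,
    cfg: VirtualSpeciesConfig,
    bias: RasterLayer | None = None,
) -> pd.DataFrame:
    """Draw presence-only records from a truth surface with sampling bias.

    Cells are drawn with replacement with probability proportional to
    ``truth * bias`` (bias 1 when absent); one uniform point is placed inside
    each drawn cell.  Records then receive a log-normal coordinate
    uncertainty (missing with probability ``p_missing_uncertainty``) and,
    with probability ``p_error_records``, one of three labelled corruptions:
    zero coordinates, longitude copied into latitude, or an exact duplicate
    of an earlier record.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = truth.grid
    weights = np.where(truth.mask, 0.0, np.nan_to_num(truth.values, nan=0.0))
    if weights.min() < -1e-12 or np.nanmax(truth.values) > 1 + 1e-12:
        raise ValueError("truth values must lie in [0,1]")
    if bias is not None:
        if bias.grid != grid:
            raise ValueError("bias layer grid mismatch")
        weights = weights * np.where(bias.mask, 0.0, np.clip(bias.values, 0.0, None))
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"no habitat: truth*bias is identically zero for {cfg.species_name}")

    flat_p = (weights / total).ravel()
    n = cfg.n_records
    cells = rng.choice(grid.n_cells, size=n, replace=True, p=flat_p)
    rows, cols = np.divmod(cells, grid.n_cols)
    lon = grid.min_lon + (cols + rng.uniform(0, 1, n)) * grid.cell_size
    lat = grid.min_lat + (rows + rng.uniform(0, 1, n)) * grid.cell_size

    unc = rng.lognormal(cfg.uncertainty_log_mean, cfg.uncertainty_log_sd, n)
    unc[rng.uniform(size=n) < cfg.p_missing_uncertainty] = np.nan
    basis = np.where(
        rng.uniform(size=n) < 0.8, "human_observation", "machine_observation"
    ).astype(object)

    flags = np.array([""] * n, dtype=object)
    corrupt = np.flatnonzero(rng.uniform(size=n) < cfg.p_error_records)
    for i in corrupt:
        kinds = ["zero_coordinates", "lon_equals_lat"]
        if i > 0:
            kinds.append("duplicate")
        kind = kinds[rng.integers(len(kinds))]
        if kind == "zero_coordinates":
            lon[i] = 0.0
            lat[i] = 0.0
        elif kind == "lon_equals_lat":
            lat[i] = lon[i]
        else:
            j = int(rng.integers(i))
            lon[i] = lon[j]
            lat[i] = lat[j]
        flags[i] = kind

    return pd.DataFrame(
        {
            "species": cfg.species_name,
            "lon": lon,
            "lat": lat,
            "coordinate_uncertainty_m": unc,
            "basis_of_record": basis,
            "family": cfg.family,
            "raw_flags": flags,
        }
    )


def climatically_favorable_region(
    stack: RasterStack,
    linear_coefficients: dict[str, float],
    size: int,
    step: int = 8,
) -> GridSpec:
    """Site a square study region over climatically suitable terrain.

    Invaded study regions are not random samples of the globe: a species is
    studied where its climate broadly fits (that is why it invaded).  This
    helper scans candidate ``size x size`` sub-extents on a coarse offset
    lattice and returns the one with the highest mean climatic linear
    predictor, emulating that premise for hierarchy experiments.
    """
    grid = stack.grid
    if size > min(grid.n_rows, grid.n_cols):
        raise ValueError("region size exceeds world grid")
    eta = np.zeros(grid.shape)
    for name, beta in linear_coefficients.items():
        eta += beta * stack[name].values
    best: tuple[float, int, int] | None = None
    for r0 in range(0, grid.n_rows - size + 1, step):
        for c0 in range(0, grid.n_cols - size + 1, step):
            m = float(eta[r0 : r0 + size, c0 : c0 + size].mean())
            if best is None or m > best[0]:
                best = (m, r0, c0)
    _, r0, c0 = best  # type: ignore[misc]
    return GridSpec(
        grid.min_lon + c0 * grid.cell_size,
        grid.min_lat + r0 * grid.cell_size,
        grid.cell_size,
        size,
        size,
    )


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as a Darwin-Core-like CSV (generator flags excluded)."""
    out = records.drop(columns=["raw_flags"], errors="ignore").rename(
        columns=_DWC_RENAME
    )
    out.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read a Darwin-Core-like occurrence CSV into internal column names."""
    df = pd.read_csv(path)
    inv = {v: k for k, v in _DWC_RENAME.items()}
    df = df.rename(columns=inv)
    missing = [c for c in ("species", "lon", "lat") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "coordinate_uncertainty_m" not in df.columns:
        df["coordinate_uncertainty_m"] = np.nan
    if "basis_of_record" not in df.columns:
        df["basis_of_record"] = "human_observation"
    if "family" not in df.columns:
        df["family"] = ""
    if "raw_flags" not in df.columns:
        df["raw_flags"] = ""
    return df[OCCURRENCE_COLUMNS]
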
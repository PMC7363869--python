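import warnings

import numpy as np
import pandas as pd
import pytest

from hiersdm.grids import GridSpec, RasterLayer, RasterStack
from hiersdm.synthetic import (
    VirtualSpeciesConfig,
    generate_environment,
    sample_occurrences,
    true_suitability,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def grid40() -> GridSpec:
    return GridSpec(0.0, 0.0, 0.25, 40, 40)


@pytest.fixture(scope="session")
def env40(grid40) -> RasterStack:
    """3 climate + 2 habitat layers plus one planted near-duplicate."""
    return generate_environment(
        grid40, n_climate=3, n_habitat=2, autocorr_range_cells=3.0,
        duplicate_pairs=1, seed=42,
    )


@pytest.fixture(scope="session")
def specialist_cfg() -> VirtualSpeciesConfig:
    """Strong-signal climate specialist used across recovery tests."""
    return VirtualSpeciesConfig(
        species_name="virtualis_fortis",
        linear_coefficients={"climate_01": 2.0, "climate_02": 2.0},
        prevalence_target=0.1,
        n_records=700,
        p_error_records=0.05,
        p_missing_uncertainty=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def specialist_world(grid40, env40, specialist_cfg):
    """(truth, records) for the specialist on the 40x40 grid."""
    truth = true_suitability(env40, specialist_cfg)
    records = sample_occurrences(truth, specialist_cfg)
    return truth, records


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_layer(grid: GridSpec, values, name: str = "x") -> RasterLayer:
    return RasterLayer(grid, name, np.asarray(values, dtype=float))


@pytest.fixture(scope="session")
def clean_records() -> pd.DataFrame:
    """Hand-built record table exercising every filter/clean branch."""
    return pd.DataFrame(
        {
            "species": ["sp"] * 8,
            "lon": [1.0, 2.0, 0.0, 12.5, 3.0, 3.0, 4.0, 5.0],
            "lat": [1.5, 2.5, 0.0, 12.5, 3.5, 3.5, 4.5, 5.5],
            "coordinate_uncertainty_m": [
                100.0, 15000.0, 50.0, 50.0, 200.0, 200.0, np.nan, 20000.0,
            ],
            "basis_of_record": [
                "human_observation", "machine_observation", "human_observation",
                "human_observation", "human_observation", "human_observation",
                "human_observation", "human_observation",
            ],
            "family": ["F"] * 8,
            "raw_flags": ["", "", "zero_coordinates", "lon_equals_lat", "",
                          "duplicate", "", ""],
        }
    )
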
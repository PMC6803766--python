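"""Shared synthetic-world fixtures (session-scoped: built once)."""

import numpy as np
import pytest

from rangeshift.grids import GridSpec
from rangeshift.synthetic import (
    ClimateConfig,
    EffortModel,
    LandscapeConfig,
    climate_covariates,
    make_climate,
    make_landscape,
    make_species_cohort,
    simulate_occupancy,
    simulate_recording,
)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(0.0, 0.0, 3, 8)  # 30 km x 80 km


@pytest.fixture(scope="session")
def small_world(small_grid):
    cfg = LandscapeConfig(grid=small_grid, autocorr_scale_km=1.0, relief_m=200.0)
    grid, landcover, elevation, solar = make_landscape(cfg, seed=101)
    return {"grid": grid, "landcover": landcover, "elevation": elevation, "solar": solar}


@pytest.fixture(scope="session")
def small_climate(small_world):
    cfg = ClimateConfig(
        grid=small_world["grid"], elevation_ha=small_world["elevation"], noise_sd_c=0.2
    )
    return make_climate(cfg, seed=102)


@pytest.fixture(scope="session")
def small_cohort():
    return make_species_cohort(
        6, ["butterflies", "dragonflies"], seed=103, baseline_rows=2
    )


@pytest.fixture(scope="session")
def small_occupancy(small_cohort, small_world, small_climate):
    cov = climate_covariates(small_climate)
    return {
        t.species: simulate_occupancy(
            t, small_world["landcover"], small_climate, seed=200 + i, covariates=cov
        )
        for i, t in enumerate(small_cohort)
    }


@pytest.fixture(scope="session")
def small_records(small_occupancy, small_cohort, small_grid):
    efforts = [
        EffortModel(scheme="butterflies", visits_per_hectad_year=30),
        EffortModel(scheme="dragonflies", visits_per_hectad_year=30),
    ]
    records, visits = simulate_recording(
        small_occupancy, efforts, small_cohort, small_grid, seed=104
    )
    return {"records": records, "visits": visits}
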
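"""Synthetic landscapes, climates, species and recording processes.

Everything downstream of raw data ingestion — effort filters, margin
estimation, habitat models, mixed models — is exercised against worlds
generated here with known ground truth: each species carries a
habitat-preference vector over the 18 land-cover classes, climate
response coefficients, a dispersal radius, a per-visit detectability
and a flight period, and the generator produces the true hectad-level
occupancy trajectory alongside the records a citizen-science recording
process would have produced from it.

Coordinates are planar km (see :mod:`rangeshift.grids`); "latitude"
downstream always means planar northing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from rangeshift.grids import (
    COARSE_KM,
    HA_KM,
    HA_PER_HECTAD,
    HECTAD_KM,
    LC_PER_HA,
    GridSpec,
)

N_CLASSES = 18

#: 23-class source land-cover legend. One class (saltwater) is discarded,
#: 14 are retained as mapped, and four aggregate classes absorb the
#: remaining eight (heather + heather grassland -> dwarf shrub heath,
#: supra-littoral/littoral rock -> coastal rock, supra-littoral/littoral
#: sediment -> coastal sediment, suburban + urban -> built-up and gardens).
SOURCE_LEGEND = [
    "broadleaved woodland",       # 0
    "coniferous woodland",        # 1
    "arable",                     # 2
    "improved grassland",         # 3
    "rough grassland",            # 4
    "neutral grassland",          # 5
    "calcareous grassland",       # 6
    "acid grassland",             # 7
    "fen marsh swamp",            # 8
    "heather",                    # 9  -> merged
    "heather grassland",          # 10 -> merged
    "bog",                        # 11
    "montane",                    # 12
    "inland rock",                # 13
    "saltwater",                  # 14 -> discarded
    "freshwater",                 # 15
    "supra-littoral rock",        # 16 -> merged
    "supra-littoral sediment",    # 17 -> merged
    "littoral rock",              # 18 -> merged
    "littoral sediment",          # 19 -> merged
    "saltmarsh",                  # 20
    "suburban",                   # 21 -> merged
    "urban",                      # 22 -> merged
]

LEGEND = [
    "broadleaved woodland",
    "coniferous woodland",
    "arable",
    "improved grassland",
    "rough grassland",
    "neutral grassland",
    "calcareous grassland",
    "acid grassland",
    "fen marsh swamp",
    "bog",
    "montane",
    "inland rock",
    "freshwater",
    "saltmarsh",
    "dwarf shrub heath",
    "coastal rock",
    "coastal sediment",
    "built-up and gardens",
]

DISCARDED_SOURCE_CODE = 14  # saltwater

#: source code -> output code; -1 marks the discarded class.
AGGREGATION_MAP = {
    0: 0, 1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6, 7: 7, 8: 8,
    9: 14, 10: 14,            # dwarf shrub heath
    11: 9, 12: 10, 13: 11,
    14: -1,                   # saltwater discarded
    15: 12,
    16: 15, 18: 15,           # coastal rock
    17: 16, 19: 16,           # coastal sediment
    20: 13,
    21: 17, 22: 17,           # built-up and gardens
}

#: study recording periods (15 years each, 25-year midpoint gap)
PERIOD1 = (1976, 1990)
PERIOD2 = (2001, 2015)
YEARS = tuple(range(1976, 2016))


def aggregate_source_classes(source: np.ndarray) -> np.ndarray:
    """Map a 23-class source raster onto the 18-class working legend.

    Pixels of the discarded class come back as -1 (excluded downstream).
    """
    lut = np.full(len(SOURCE_LEGEND), -1, dtype=np.int16)
    for src, dst in AGGREGATION_MAP.items():
        lut[src] = dst
    out = lut[np.asarray(source, dtype=np.intp)]
    return out


@dataclass
class LandCoverMap:
    """Categorical 25 m land-cover raster over the 18-class legend.

    ``classes`` holds codes 0..17, or -1 for pixels of the discarded
    source class (absent from generated maps unless requested).
    """

    classes: np.ndarray
    legend: tuple[str, ...] = tuple(LEGEND)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)

    @property
    def n_classes(self) -> int:
        return len(self.legend)

    def class_fractions(self) -> np.ndarray:
        """Frequencies of the 18 classes over valid pixels."""
        valid = self.classes[self.classes >= 0]
        return np.bincount(valid, minlength=self.n_classes) / valid.size

    def ha_class_fractions(self) -> np.ndarray:
        """Per-1-ha-pixel class fractions, shaped (ny_ha, nx_ha, 18)."""
        ny, nx = self.classes.shape
        blocks = self.classes.reshape(ny // LC_PER_HA, LC_PER_HA, nx // LC_PER_HA, LC_PER_HA)
        blocks = blocks.transpose(0, 2, 1, 3).reshape(ny // LC_PER_HA, nx // LC_PER_HA, LC_PER_HA**2)
        out = np.zeros(blocks.shape[:2] + (self.n_classes,))
        for k in range(self.n_classes):
            out[..., k] = (blocks == k).mean(axis=-1)
        return out


@dataclass
class SpeciesTruth:
    """Ground truth for one simulated species."""

    species: str
    group: str
    habitat_preference: np.ndarray  # length 18, log-odds
    climate_response: np.ndarray  # length 3
    baseline_rows: int  # number of southern hectad rows initially occupied
    dispersal_km_per_year: float
    detectability: float  # per-visit detection probability, in (0, 1]
    flight_window: tuple[int, int]  # day-of-year window, inclusive

    def __post_init__(self) -> None:
        self.habitat_preference = np.asarray(self.habitat_preference, dtype=float)
        self.climate_response = np.asarray(self.climate_response, dtype=float)
        if not np.all(np.isfinite(self.habitat_preference)):
            raise ValueError("habitat preference must be finite")
        if not (0 < self.detectability <= 1):
            raise ValueError("detectability must lie in (0, 1]")
        lo, hi = self.flight_window
        if not (1 <= lo <= 366 and 1 <= hi <= 366):
            raise ValueError("flight window must lie within [1, 366]")


@dataclass
class LandscapeConfig:
    """Controls for :func:`make_landscape`."""

    grid: GridSpec
    class_weights: np.ndarray | None = None  # mixing weights over 18 classes
    autocorr_scale_km: float = 2.0  # patch scale; 0 -> i.i.d. pixels
    relief_m: float = 300.0  # elevation standard deviation target
    elevation_scale_km: float = 10.0
    solar_ratio_sd: float = 0.15

    def weights(self) -> np.ndarray:
        if self.class_weights is None:
            w = np.ones(N_CLASSES)
        else:
            w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (N_CLASSES,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("class weights must be 18 non-negative values")
        return w / w.sum()


def _smooth_standard_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    f = rng.standard_normal(shape)
    if sigma_px > 0:
        f = gaussian_filter(f, sigma_px, mode="reflect")
        f = (f - f.mean()) / max(f.std(), 1e-12)
    return f


def make_landscape(config: LandscapeConfig, seed: int):
    """Generate the region's land cover, elevation and solar-ratio rasters.

    Returns ``(grid, LandCoverMap, elevation_ha, solar_ratio_ha)``.
    Land cover is drawn at 25 m over the 18-class legend: i.i.d.
    categorical draws when ``autocorr_scale_km`` is 0, otherwise an
    argmax over spatially smoothed Gaussian fields biased by the class
    mixing weights, which yields contiguous patches.  Elevation (m) and
    the topographic solar ratio SR_topo/SR_flat are 1-ha rasters; the
    ratio lies in (0, 1.5].
    """
    grid = config.grid
    rng = np.random.default_rng(seed)
    w = config.weights()

    lc_shape = grid.lc_shape
    if config.autocorr_scale_km <= 0:
        classes = rng.choice(N_CLASSES, size=lc_shape, p=w).astype(np.int16)
    else:
        # class fields are smoothed at the 1-ha grain and block-upsampled:
        # patches are >= 1 km across, so 25 m noise resolution adds nothing
        sigma_px = config.autocorr_scale_km / HA_KM
        ha_shape = grid.ha_shape
        score = np.empty((N_CLASSES,) + ha_shape)
        for k in range(N_CLASSES):
            g = _smooth_standard_field(rng, ha_shape, sigma_px)
            score[k] = np.log(w[k] + 1e-300) + 1.2828 * g  # Gumbel sd
        classes_ha = score.argmax(axis=0).astype(np.int16)
        classes = np.kron(classes_ha, np.ones((LC_PER_HA, LC_PER_HA), dtype=np.int16))

    ha_shape = grid.ha_shape
    elev = _smooth_standard_field(rng, ha_shape, config.elevation_scale_km / HA_KM)
    elevation = np.clip(config.relief_m * (elev - elev.min()) / max(np.ptp(elev), 1e-12), 0, None)

    sr = 1.0 + config.solar_ratio_sd * _smooth_standard_field(rng, ha_shape, 5.0)
    solar_ratio = np.clip(sr, 1e-3, 1.5)

    return grid, LandCoverMap(classes), elevation, solar_ratio


# ---------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------

#: mean monthly temperature anomaly (deg C) about the annual mean, Jan..Dec
_SEASONAL_T = np.array([-4.5, -4.0, -2.5, 0.0, 3.0, 5.5, 7.0, 6.5, 4.0, 1.0, -2.0, -4.0])
_SEASONAL_RAIN = np.array([95, 70, 75, 60, 55, 60, 65, 70, 75, 95, 100, 100], dtype=float)
_SEASONAL_SUNFRAC = np.array(
    [0.22, 0.27, 0.30, 0.36, 0.38, 0.37, 0.36, 0.37, 0.34, 0.28, 0.24, 0.20]
)

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class ClimateConfig:
    """Controls for :func:`make_climate`.

    The emulated structure is a latitudinal gradient plus a linear
    warming trend, an elevational lapse and i.i.d. monthly noise —
    enough for the downscaling and margin machinery to have a recoverable
    signal, not a weather generator.
    """

    grid: GridSpec
    base_temp_c: float = 8.5  # regional mean annual temperature in period 1
    gradient_c_per_100km: float = -0.6  # cooling northwards
    trend_c_per_year: float = 0.032
    lapse_c_per_km: float = -6.0
    diurnal_range_c: float = 7.0
    noise_sd_c: float = 0.0
    base_rain_scale: float = 1.0
    rain_noise_sd: float = 0.0
    sun_noise_sd: float = 0.0
    years: tuple[int, ...] = YEARS
    elevation_ha: np.ndarray | None = None  # aggregated to 5 km if given


@dataclass
class ClimateCube:
    """Monthly climate grids at the 5 km coarse grain.

    Arrays are shaped ``(n_years, 12, ny, nx)``; temperatures in deg C,
    rain in mm/month, sunshine in hours/month.
    """

    grid: GridSpec
    years: tuple[int, ...]
    tmin: np.ndarray
    tmax: np.ndarray
    rain: np.ndarray
    sun_hours: np.ndarray
    elevation: np.ndarray  # 5 km grain

    def year_index(self, year: int) -> int:
        return self.years.index(year)

    def annual_mean_temp(self) -> np.ndarray:
        """(n_years, ny, nx) calendar-year mean of (tmin+tmax)/2."""
        tmean = 0.5 * (self.tmin + self.tmax)
        return np.average(tmean, axis=1, weights=DAYS_IN_MONTH)

    def period_mean_temp(self, period: tuple[int, int]) -> np.ndarray:
        sel = [i for i, y in enumerate(self.years) if period[0] <= y <= period[1]]
        return self.annual_mean_temp()[sel].mean(axis=0)


def coarsen_to_5km(array_ha: np.ndarray) -> np.ndarray:
    """Block-average a 1-ha raster onto the 5 km climate grid."""
    f = int(COARSE_KM / HA_KM)
    ny, nx = array_ha.shape
    return array_ha.reshape(ny // f, f, nx // f, f).mean(axis=(1, 3))


def make_climate(config: ClimateConfig, seed: int) -> ClimateCube:
    """Generate coarse monthly climate grids for the simulation span.

    Temperature at (northing, elevation, year, month) is an affine
    function plus optional noise:

    ``T = base + seasonal[month] + g*(northing - mid) + w*(year - y0)
    + lapse*elev_km (+ noise)``

    with the diurnal range split symmetrically into tmin/tmax.  Rainfall
    and sunshine hours follow fixed seasonal profiles with optional
    multiplicative noise; sunshine hours are capped by day length.
    """
    grid = config.grid
    rng = np.random.default_rng(seed)
    north, _ = grid.coarse_centres_1d()
    ny, nx = grid.coarse_shape
    if config.elevation_ha is not None:
        elev5 = coarsen_to_5km(config.elevation_ha)
    else:
        elev5 = np.zeros((ny, nx))

    years = np.asarray(config.years)
    mid_north = 0.5 * (north[0] + north[-1])
    y0 = years[0]

    northing = np.broadcast_to(north[:, None], (ny, nx))
    spatial = (
        config.gradient_c_per_100km * (northing - mid_north) / 100.0
        + config.lapse_c_per_km * elev5 / 1000.0
    )

    n_years = len(years)
    shape = (n_years, 12, ny, nx)
    tmean = (
        config.base_temp_c
        + _SEASONAL_T[None, :, None, None]
        + spatial[None, None]
        + config.trend_c_per_year * (years - y0)[:, None, None, None]
    )
    if config.noise_sd_c > 0:
        tmean = tmean + rng.normal(0, config.noise_sd_c, size=shape)
    half = config.diurnal_range_c / 2.0
    tmin = tmean - half
    tmax = tmean + half

    rain = config.base_rain_scale * _SEASONAL_RAIN[None, :, None, None] * np.ones(shape)
    if config.rain_noise_sd > 0:
        rain = rain * np.exp(rng.normal(0, config.rain_noise_sd, size=shape))

    # day length from the region's nominal latitude (see climate module)
    from rangeshift.climate import day_length_hours

    daylen = np.array(
        [day_length_hours(m + 1, northing_km=mid_north) for m in range(12)]
    )
    frac = _SEASONAL_SUNFRAC[None, :, None, None] * np.ones(shape)
    if config.sun_noise_sd > 0:
        frac = np.clip(frac + rng.normal(0, config.sun_noise_sd, size=shape), 0, 1)
    sun = frac * daylen[None, :, None, None] * DAYS_IN_MONTH[None, :, None, None]

    return ClimateCube(
        grid=grid,
        years=tuple(int(y) for y in years),
        tmin=tmin,
        tmax=tmax,
        rain=rain,
        sun_hours=sun,
        elevation=elev5,
    )


# ---------------------------------------------------------------------
# species and occupancy
# ---------------------------------------------------------------------


def make_species_cohort(
    n_species: int,
    groups: list[str],
    seed: int,
    *,
    concentration_range: tuple[float, float] = (0.5, 4.0),
    dispersal_range: tuple[float, float] = (5.0, 20.0),
    detectability_range: tuple[float, float] = (0.3, 0.9),
    baseline_rows: int = 3,
    warm_response: float = 1.0,
) -> list[SpeciesTruth]:
    """Draw a cohort of species truths spanning specialist to generalist.

    Preference concentration (the spread of the habitat log-odds vector)
    varies across the cohort; each species prefers a random subset of
    classes.  All species respond positively to accumulated warmth with
    coefficient ``warm_response`` (scaled per species), the minimal
    structure needed for warming-driven expansion.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_species):
        conc = rng.uniform(*concentration_range)
        pref = rng.normal(0.0, 1.0, N_CLASSES)
        pref = conc * (pref - pref.mean())
        resp = np.array([0.2 * rng.uniform(0.5, 1.5), warm_response * rng.uniform(0.5, 1.5), 0.1])
        cohort.append(
            SpeciesTruth(
                species=f"sp{i:03d}",
                group=groups[i % len(groups)],
                habitat_preference=pref,
                climate_response=resp,
                baseline_rows=baseline_rows,
                dispersal_km_per_year=rng.uniform(*dispersal_range),
                detectability=rng.uniform(*detectability_range),
                flight_window=(int(rng.integers(120, 160)), int(rng.integers(210, 250))),
            )
        )
    return cohort


def climate_covariates(climate: ClimateCube) -> np.ndarray:
    """Standardised hectad x year climate covariates for the truth model.

    Three covariates per hectad-year: winter-ish minimum (annual minimum
    of monthly tmin), accumulated warmth (sum of monthly mean excess
    over 5 deg C) and rain total, each z-scored over the whole cube.
    Shaped ``(n_years, n_hectads_north, n_hectads_east, 3)``.
    """
    grid = climate.grid
    f = int(HECTAD_KM / COARSE_KM)

    def to_hectad(a):  # (years, ny5, nx5) -> (years, nyh, nxh)
        n_years, ny, nx = a.shape
        return a.reshape(n_years, ny // f, f, nx // f, f).mean(axis=(2, 4))

    tmean = 0.5 * (climate.tmin + climate.tmax)
    winter_min = climate.tmin.min(axis=1)
    warmth = (np.clip(tmean - 5.0, 0, None) * DAYS_IN_MONTH[None, :, None, None]).sum(axis=1)
    rain = climate.rain.sum(axis=1)

    cov = np.stack([to_hectad(winter_min), to_hectad(warmth), to_hectad(rain)], axis=-1)
    mu = cov.mean(axis=(0, 1, 2), keepdims=True)
    sd = cov.std(axis=(0, 1, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (cov - mu) / sd


def hectad_suitability(
    truth: SpeciesTruth, landcover: LandCoverMap, covariates: np.ndarray
) -> np.ndarray:
    """Mean habitat-climate suitability per hectad and year.

    Suitability of a pixel is the inverse logit of the class preference
    plus the climate term; the hectad value averages over the class
    composition (climate is constant within a hectad at this grain).
    Shaped ``(n_years, nyh, nxh)``.
    """
    n_years, nyh, nxh, _ = covariates.shape
    counts = np.zeros((nyh, nxh, N_CLASSES))
    lc = landcover.classes
    fy = lc.shape[0] // nyh
    fx = lc.shape[1] // nxh
    blocks = lc.reshape(nyh, fy, nxh, fx).transpose(0, 2, 1, 3).reshape(nyh, nxh, fy * fx)
    for k in range(N_CLASSES):
        counts[..., k] = (blocks == k).mean(axis=-1)

    clim = covariates @ truth.climate_response  # (years, nyh, nxh)
    # mean over classes of expit(pref_k + clim), weighted by composition
    suit = np.zeros((n_years, nyh, nxh))
    for k in range(N_CLASSES):
        wk = counts[..., k]
        if wk.max() == 0:
            continue
        suit += wk[None] * expit(truth.habitat_preference[k] + clim)
    return suit


def simulate_occupancy(
    truth: SpeciesTruth,
    landcover: LandCoverMap,
    climate: ClimateCube,
    years: tuple[int, ...] | None = None,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-simulate true hectad occupancy, one annual step per year.

    The update rule is deliberately minimal: an occupied hectad persists
    with probability equal to its mean suitability that year; an
    unoccupied hectad within the species' dispersal radius of an
    occupied one is colonised with probability equal to its mean
    suitability.  Returns a boolean array ``(n_years, nyh, nxh)``.
    """
    grid = climate.grid
    years = years or climate.years
    if covariates is None:
        covariates = climate_covariates(climate)
    suit = hectad_suitability(truth, landcover, covariates)
    year_idx = [climate.years.index(y) for y in years]

    rng = np.random.default_rng(seed)
    nyh, nxh = grid.hectad_shape
    north, east = grid.hectad_centres()

    occ = np.zeros((len(years), nyh, nxh), dtype=bool)
    occ[0, : truth.baseline_rows, :] = True

    radius = truth.dispersal_km_per_year
    coords = np.stack([north.ravel(), east.ravel()], axis=1)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    reachable = d2 <= radius**2  # includes self

    for t in range(1, len(years)):
        s = suit[year_idx[t]].ravel()
        prev = occ[t - 1].ravel()
        persist = prev & (rng.random(prev.size) < s)
        frontier = (~prev) & (reachable[:, prev].any(axis=1))
        colonise = frontier & (rng.random(prev.size) < s)
        occ[t] = (persist | colonise).reshape(nyh, nxh)
    return occ


# ---------------------------------------------------------------------
# recording process
# ---------------------------------------------------------------------


@dataclass
class EffortModel:
    """Recorder-visit process for one recording scheme.

    ``visits_per_hectad_year`` is the expected number of scheme visits
    per hectad per year (Poisson); ``spatial_multiplier`` (hectad grid)
    scales it regionally, so effort 0 somewhere means no visits there.
    ``exhaustive`` instead schedules one visit to every 1-ha pixel every
    year (used to make recording a census in tests).
    """

    scheme: str
    visits_per_hectad_year: float = 5.0
    spatial_multiplier: np.ndarray | None = None
    exhaustive: bool = False
    visit_day_window: tuple[int, int] = (1, 365)


def _dates_from_days(year: int, days: np.ndarray) -> np.ndarray:
    base = np.datetime64(f"{year}-01-01")
    return base + (days - 1).astype("timedelta64[D]")


def simulate_recording(
    occupancy: dict[str, np.ndarray],
    effort: EffortModel | list[EffortModel],
    truths: list[SpeciesTruth],
    grid: GridSpec,
    seed: int,
    years: tuple[int, ...] = YEARS,
    occupancy_years: tuple[int, ...] = YEARS,
    hectad_precision_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate scheme visits and the records they generate.

    Every visit picks a uniform 1-ha pixel within its hectad and a
    uniform day within the effort model's day window.  A species of the
    visited scheme is recorded when its hectad is truly occupied that
    year, the visit date falls inside its flight period, and a
    per-visit Bernoulli(detectability) succeeds.  Records therefore form
    a subset of (occupied pixel, visit) pairs; the visit table lists
    every visit regardless of detection.

    Returns ``(records, visits)`` DataFrames; records have columns
    species, scheme, easting_km, northing_km, precision, date.
    """
    rng = np.random.default_rng(seed)
    efforts = effort if isinstance(effort, list) else [effort]
    nyh, nxh = grid.hectad_shape

    visit_rows: list[tuple] = []
    record_rows: list[tuple] = []

    for eff in efforts:
        mult = np.ones((nyh, nxh)) if eff.spatial_multiplier is None else np.asarray(eff.spatial_multiplier)
        scheme_species = [t for t in truths if t.group == eff.scheme]
        for year in years:
            ti = occupancy_years.index(year)  # row of the occupancy arrays
            if eff.exhaustive:
                ny_ha, nx_ha = grid.ha_shape
                iy, ix = np.mgrid[0:ny_ha, 0:nx_ha]
                iy, ix = iy.ravel(), ix.ravel()
                keep = mult[iy // HA_PER_HECTAD, ix // HA_PER_HECTAD] > 0
                iy, ix = iy[keep], ix[keep]
                days = rng.integers(eff.visit_day_window[0], eff.visit_day_window[1] + 1, iy.size)
            else:
                lam = eff.visits_per_hectad_year * mult
                n_visits = rng.poisson(lam)
                total = int(n_visits.sum())
                if total == 0:
                    continue
                hy, hx = np.nonzero(n_visits)
                reps = n_visits[hy, hx]
                hy = np.repeat(hy, reps)
                hx = np.repeat(hx, reps)
                iy = hy * HA_PER_HECTAD + rng.integers(0, HA_PER_HECTAD, total)
                ix = hx * HA_PER_HECTAD + rng.integers(0, HA_PER_HECTAD, total)
                days = rng.integers(eff.visit_day_window[0], eff.visit_day_window[1] + 1, total)

            north = grid.origin_northing_km + (iy + 0.5) * HA_KM
            east = grid.origin_easting_km + (ix + 0.5) * HA_KM
            dates = _dates_from_days(year, days)
            visit_rows.extend(zip([eff.scheme] * len(iy), east, north, dates))

            hy = iy // HA_PER_HECTAD
            hx = ix // HA_PER_HECTAD
            for truth in scheme_species:
                occ = occupancy[truth.species]
                present = occ[ti, hy, hx]
                lo, hi = truth.flight_window
                in_window = (days >= lo) & (days <= hi)
                detected = present & in_window & (rng.random(len(iy)) < truth.detectability)
                if not detected.any():
                    continue
                de, dn, dd = east[detected], north[detected], dates[detected]
                prec = np.where(
                    rng.random(detected.sum()) < hectad_precision_fraction, "hectad", "ha"
                )
                for k in range(len(de)):
                    if prec[k] == "hectad":
                        hcy, hcx = grid.hectad_of_point(de[k], dn[k])
                        cn, ce = grid.hectad_centre(hcy, hcx)
                        record_rows.append((truth.species, eff.scheme, ce, cn, "hectad", dd[k]))
                    else:
                        record_rows.append((truth.species, eff.scheme, de[k], dn[k], "ha", dd[k]))

    visits = pd.DataFrame(visit_rows, columns=["scheme", "easting_km", "northing_km", "date"])
    records = pd.DataFrame(
        record_rows,
        columns=["species", "scheme", "easting_km", "northing_km", "precision", "date"],
    )
    for df in (visits, records):
        if len(df):
            df["date"] = pd.to_datetime(df["date"])
    return records, visits


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    return df
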
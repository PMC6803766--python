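"""Recorder-effort controls and species inclusion criteria.

Citizen-science records are uneven in space and time, so range-shift
estimates are restricted to 'well-recorded' hectads: those where the
recorded richness of a taxonomic group reaches a threshold fraction
(10% for the main analysis, 25% for the recording-intensity metric) of
the regional species pool — the distinct species of the group recorded
across the nearest 100 hectads — in *both* recording periods.  Species
enter the analysis only if their historical distribution is
concentrated in the warm half of the region, away from the northern
coast, and supported by enough well-recorded hectads and precise
records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rangeshift.grids import GridSpec
from rangeshift.synthetic import PERIOD1, PERIOD2


def hectad_index(records: pd.DataFrame, grid: GridSpec) -> pd.Series:
    """Scalar hectad id for each record (row-major from the SW corner)."""
    iy, ix = grid.hectad_of_point(
        records["easting_km"].to_numpy(), records["northing_km"].to_numpy()
    )
    return pd.Series(grid.hectad_id(iy, ix), index=records.index, name="hectad")


def assign_period(dates: pd.Series, periods=(PERIOD1, PERIOD2)) -> pd.Series:
    """Period label (0-based index) per record; -1 outside all periods."""
    years = pd.to_datetime(dates).dt.year
    out = pd.Series(-1, index=dates.index)
    for i, (y0, y1) in enumerate(periods):
        out[(years >= y0) & (years <= y1)] = i
    return out


def _presence_matrix(records: pd.DataFrame, grid: GridSpec) -> tuple[np.ndarray, list[str]]:
    """Boolean (n_hectads, n_species) presence from any-period records."""
    species = sorted(records["species"].unique())
    sp_idx = {s: i for i, s in enumerate(species)}
    pres = np.zeros((grid.n_hectads, len(species)), dtype=bool)
    hid = hectad_index(records, grid)
    pres[hid.to_numpy(), records["species"].map(sp_idx).to_numpy()] = True
    return pres, species


def _neighbour_sets(grid: GridSpec, n_pool: int = 100) -> np.ndarray:
    """Indices of the nearest ``n_pool`` hectads per focal hectad.

    The focal hectad is included; ties in centroid distance break by
    hectad id, so identical neighbourhoods give identical pools.
    """
    north, east = grid.hectad_centres()
    coords = np.stack([north.ravel(), east.ravel()], axis=1)
    n = len(coords)
    k = min(n_pool, n)
    if n < n_pool:
        warnings.warn(f"region has {n} hectads < pool size {n_pool}; using all")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    ids = np.arange(n)
    # lexicographic (distance, id) ordering per row
    order = np.lexsort((np.broadcast_to(ids, (n, n)), d2), axis=1)
    return order[:, :k]


def regional_pool(
    records: pd.DataFrame,
    grid: GridSpec,
    group: str,
    hectad: int | None = None,
    n_pool: int = 100,
) -> np.ndarray | int:
    """Regional species pool per hectad for one group.

    The pool is the number of distinct species of the group recorded
    anywhere in the nearest ``n_pool`` hectads, using *all* records of
    the group regardless of period or other inclusion criteria.
    Returns the full per-hectad array, or a single count if ``hectad``
    (scalar id) is given.
    """
    sub = records[records["scheme"] == group]
    pres, _ = _presence_matrix(sub, grid)
    nbrs = _neighbour_sets(grid, n_pool)
    pools = np.array([pres[nbrs[h]].any(axis=0).sum() for h in range(grid.n_hectads)])
    if hectad is not None:
        return int(pools[hectad])
    return pools


@dataclass
class WellRecordedSet:
    """Hectads passing the both-period richness threshold for one group."""

    group: str
    threshold: float
    periods: tuple = (PERIOD1, PERIOD2)
    hectads: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pools: np.ndarray | None = None

    def __contains__(self, hectad_id: int) -> bool:
        return bool(np.isin(hectad_id, self.hectads))


def _period_richness(records: pd.DataFrame, grid: GridSpec, periods) -> np.ndarray:
    """(n_periods, n_hectads) distinct-species counts per period."""
    rich = np.zeros((len(periods), grid.n_hectads), dtype=int)
    period = assign_period(records["date"], periods)
    hid = hectad_index(records, grid)
    for i in range(len(periods)):
        sub = records[period == i]
        if len(sub):
            grp = sub.assign(hectad=hid[period == i]).groupby("hectad")["species"].nunique()
            rich[i, grp.index.to_numpy()] = grp.to_numpy()
    return rich


def well_recorded(
    records: pd.DataFrame,
    grid: GridSpec,
    group: str,
    threshold: float = 0.10,
    periods=(PERIOD1, PERIOD2),
    n_pool: int = 100,
) -> WellRecordedSet:
    """Hectads where the group's recorded richness reaches the threshold.

    A hectad qualifies when, in *each* period, the distinct species
    recorded there number at least ``threshold`` times the regional
    pool (boundary inclusive) and at least one species was recorded.
    Lowering the threshold never removes a hectad.
    """
    sub = records[records["scheme"] == group]
    pools = regional_pool(records, grid, group, n_pool=n_pool)
    rich = _period_richness(sub, grid, periods)
    ok = np.ones(grid.n_hectads, dtype=bool)
    for i in range(len(periods)):
        ok &= (rich[i] >= threshold * pools) & (rich[i] > 0)
    return WellRecordedSet(
        group=group,
        threshold=threshold,
        periods=tuple(periods),
        hectads=np.nonzero(ok)[0],
        pools=pools,
    )


def recording_intensity(
    records: pd.DataFrame,
    grid: GridSpec,
    group: str,
    threshold: float = 0.25,
    periods=(PERIOD1, PERIOD2),
    n_pool: int = 100,
) -> int:
    """Number of hectads meeting the (default 25%) both-period threshold.

    This is the geographic-coverage metric used to rank groups in the
    recording-intensity sensitivity sweep.
    """
    return len(well_recorded(records, grid, group, threshold, periods, n_pool).hectads)


def inclusion_filter(
    records: pd.DataFrame,
    grid: GridSpec,
    hectad_temp_p1: np.ndarray,
    well_sets: dict[str, WellRecordedSet],
    *,
    warm_fraction: float = 0.90,
    coast_buffer_km: float = 100.0,
    min_well_hectads: int = 20,
    min_presence_pixels: int = 200,
    periods=(PERIOD1, PERIOD2),
    species_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species eligibility verdicts with machine-readable reason codes.

    A species is eligible when (i) at least ``warm_fraction`` of its
    first-period occupied hectads fall in the warmest half of the region
    (ranked by first-period mean annual temperature), (ii) none of its
    first-period records lie within ``coast_buffer_km`` of the region's
    northern boundary, (iii) it occupies at least ``min_well_hectads``
    well-recorded hectads in both periods, and (iv) it has at least
    ``min_presence_pixels`` distinct precise (1-ha) presence pixels.
    External status flags (non-native, vagrant, extinct …) are boolean
    input columns indexed by species, not computed here.

    Reason codes: ``no-records``, ``warm-half``, ``coast-buffer``,
    ``few-hectads``, ``few-pixels``, plus the name of any true flag.
    """
    temps = np.asarray(hectad_temp_p1, dtype=float).ravel()
    if temps.size != grid.n_hectads:
        raise ValueError("one first-period temperature per hectad required")
    order = np.lexsort((np.arange(temps.size), -temps))
    warm_ids = set(order[: temps.size // 2].tolist())

    df = records.copy()
    df["hectad"] = hectad_index(df, grid)
    df["period"] = assign_period(df["date"], periods)

    rows = []
    for species, sp in df.groupby("species"):
        group = sp["scheme"].iloc[0]
        reasons: list[str] = []
        if species_flags is not None and species in species_flags.index:
            for col in species_flags.columns:
                if bool(species_flags.loc[species, col]):
                    reasons.append(col)
        p1 = sp[sp["period"] == 0]
        if len(p1) == 0:
            reasons.append("no-records")
            warm_ok = coast_ok = False
        else:
            hecs = p1["hectad"].unique()
            warm_ok = np.mean([h in warm_ids for h in hecs]) >= warm_fraction
            if not warm_ok:
                reasons.append("warm-half")
            coast_ok = p1["northing_km"].max() <= grid.north_edge_km - coast_buffer_km
            if not coast_ok:
                reasons.append("coast-buffer")

        ws = well_sets.get(group)
        n_well = []
        for i in range(len(periods)):
            occ = sp[sp["period"] == i]["hectad"].unique()
            n_well.append(int(np.isin(occ, ws.hectads).sum()) if ws is not None else 0)
        if min(n_well) < min_well_hectads:
            reasons.append("few-hectads")

        ha = sp[sp["precision"] == "ha"]
        n_pixels = len(ha[["easting_km", "northing_km"]].drop_duplicates())
        if n_pixels < min_presence_pixels:
            reasons.append("few-pixels")

        rows.append(
            {
                "species": species,
                "group": group,
                "eligible": len(reasons) == 0,
                "reasons": ";".join(reasons),
                "n_well_hectads_p1": n_well[0],
                "n_well_hectads_p2": n_well[-1],
                "n_presence_pixels": n_pixels,
            }
        )
    return pd.DataFrame(rows).set_index("species")
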
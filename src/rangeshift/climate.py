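"""Downscaling of coarse monthly climate and annual bioclimatic variables.

Monthly 5 km grids of minimum/maximum temperature, rainfall and
sunshine hours are interpolated to 1-ha resolution by kriging —
universal kriging with a linear elevation drift for temperatures,
ordinary kriging for rainfall and sunshine — using per-field variograms
(spherical vs exponential, whichever fits the empirical variogram with
the lower SSE, 100 km distance cutoff) and the nearest 30 source
points.  Maximum temperatures are adjusted for topographic solar
radiation by rescaling the diurnal range with the ratio of terrain to
flat-surface radiation.  Three annual variables are then accumulated
over a September-anchored 12-month cycle: minimum winter temperature,
degree-days above 5 deg C, and the ratio of annual rainfall to
potential evapotranspiration (Thornthwaite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
#: mid-month day of year, Jan..Dec
_MID_MONTH_DOY = np.cumsum(DAYS_IN_MONTH) - DAYS_IN_MONTH // 2

#: nominal geographic anchoring of the planar grid: latitude in degrees
#: at northing REF_NORTHING_KM, one degree per ~111.32 km.
REF_LAT_DEG = 54.0
REF_NORTHING_KM = 500.0
KM_PER_DEG_LAT = 111.32


def northing_to_latitude(northing_km) -> np.ndarray:
    return REF_LAT_DEG + (np.asarray(northing_km, dtype=float) - REF_NORTHING_KM) / KM_PER_DEG_LAT


def day_length_hours(month: int, northing_km=None, lat_deg=None) -> float:
    """Astronomical day length (hours) at mid-month for a nominal latitude."""
    if lat_deg is None:
        lat_deg = northing_to_latitude(REF_NORTHING_KM if northing_km is None else northing_km)
    doy = _MID_MONTH_DOY[month - 1]
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    phi = np.deg2rad(np.asarray(lat_deg, dtype=float))
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    return float(24.0 / np.pi * np.arccos(cos_omega)) if np.ndim(cos_omega) == 0 else (
        24.0 / np.pi * np.arccos(cos_omega)
    )


# ---------------------------------------------------------------------
# variograms
# ---------------------------------------------------------------------


@dataclass
class VariogramFit:
    """Fitted variogram model chosen between spherical and exponential."""

    model: str  # "spherical" or "exponential"
    nugget: float
    sill: float  # total sill (nugget + partial sill)
    range_km: float
    sse: float
    cutoff_km: float = 100.0
    degenerate: bool = False  # constant field: pure nugget, sill 0

    @property
    def partial_sill(self) -> float:
        return self.sill - self.nugget

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        c = self.partial_sill
        r = self.range_km
        if self.model == "spherical":
            x = np.clip(h / r, 0, 1)
            g = self.nugget + c * (1.5 * x - 0.5 * x**3)
        else:
            g = self.nugget + c * (1 - np.exp(-3.0 * h / r))
        return np.where(h > 0, g, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) = sill."""
        h = np.asarray(h, dtype=float)
        return np.where(h > 0, self.sill - self.semivariance(h), self.sill)


def empirical_variogram(
    points: np.ndarray, values: np.ndarray, cutoff_km: float = 100.0, n_bins: int = 15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram up to the distance cutoff.

    Returns (bin centres, semivariances, pair counts); empty bins are
    dropped.  Bins are equal-width, a deliberate simple choice.
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(z), k=1)
    d = d[iu]
    sv = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    keep = d <= cutoff_km
    d, sv = d[keep], sv[keep]
    edges = np.linspace(0, cutoff_km, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sv, minlength=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    return centres[nonempty], sums[nonempty] / counts[nonempty], counts[nonempty]


def _model_gamma(model: str, h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    if model == "spherical":
        x = np.clip(h / rng, 0, 1)
        return nugget + psill * (1.5 * x - 0.5 * x**3)
    return nugget + psill * (1 - np.exp(-3.0 * h / rng))


def fit_variogram(
    points: np.ndarray,
    values: np.ndarray,
    cutoff_km: float = 100.0,
    n_bins: int = 15,
) -> VariogramFit:
    """Fit spherical and exponential variograms; keep the lower-SSE model.

    Requires at least 10 points.  A spatially constant field yields a
    degenerate pure-nugget fit (sill 0) flagged as such; kriging with it
    reproduces the constant.
    """
    z = np.asarray(values, dtype=float)
    if len(z) < 10:
        raise ValueError("variogram fitting needs at least 10 points")
    if np.ptp(z) == 0:
        return VariogramFit("spherical", 0.0, 0.0, cutoff_km, 0.0, cutoff_km, degenerate=True)

    h, gamma, counts = empirical_variogram(points, values, cutoff_km, n_bins)
    var0 = max(z.var(), 1e-12)
    best: VariogramFit | None = None
    for model in ("spherical", "exponential"):

        def resid(p):
            return _model_gamma(model, h, p[0], p[1], p[2]) - gamma

        x0 = np.array([0.0, var0, max(cutoff_km / 3, 1e-3)])
        sol = least_squares(
            resid,
            x0,
            bounds=([0, 1e-12, 1e-3], [np.inf, np.inf, 10 * cutoff_km]),
            method="trf",
        )
        sse = float((sol.fun**2).sum())
        fit = VariogramFit(
            model,
            float(sol.x[0]),
            float(sol.x[0] + sol.x[1]),
            float(sol.x[2]),
            sse,
            cutoff_km,
        )
        if best is None or fit.sse < best.sse:
            best = fit
    return best


# ---------------------------------------------------------------------
# kriging
# ---------------------------------------------------------------------


def krige(
    source_points: np.ndarray,
    source_values: np.ndarray,
    target_points: np.ndarray,
    variogram: VariogramFit,
    source_drift: np.ndarray | None = None,
    target_drift: np.ndarray | None = None,
    n_neighbours: int = 30,
) -> np.ndarray:
    """Krige a field to target points from the nearest source points.

    Ordinary kriging when no drift is supplied; universal kriging with a
    linear drift (e.g. elevation) when ``source_drift``/``target_drift``
    are given.  With a zero nugget, prediction at a source location
    returns the observed value exactly, and a drift-linear noiseless
    field is recovered exactly (the unbiasedness constraints force the
    weights to reproduce any function in the drift basis).
    """
    pts = np.asarray(source_points, dtype=float)
    z = np.asarray(source_values, dtype=float)
    tgt = np.atleast_2d(np.asarray(target_points, dtype=float))
    if len(z) < 2:
        raise ValueError("kriging needs at least 2 source points")
    if (source_drift is None) != (target_drift is None):
        raise ValueError("drift must be given for both sources and targets")

    if variogram.degenerate or variogram.sill <= 0:
        return np.full(len(tgt), z[0] if np.ptp(z) == 0 else z.mean())

    k = min(n_neighbours, len(z))
    tree = cKDTree(pts)
    _, nbr = tree.query(tgt, k=k)
    nbr = np.atleast_2d(nbr)

    sd = None if source_drift is None else np.asarray(source_drift, dtype=float)
    td = None if target_drift is None else np.atleast_1d(np.asarray(target_drift, dtype=float))

    out = np.empty(len(tgt))
    # targets sharing a neighbour set share the kriging matrix factorisation
    order = np.lexsort(nbr.T[::-1])
    sorted_nbr = nbr[order]
    boundaries = np.any(np.diff(sorted_nbr, axis=0) != 0, axis=1)
    group_starts = np.concatenate([[0], np.nonzero(boundaries)[0] + 1, [len(order)]])

    for gi in range(len(group_starts) - 1):
        rows = order[group_starts[gi] : group_starts[gi + 1]]
        idx = nbr[rows[0]]
        p = pts[idx]
        d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
        C = variogram.covariance(d)
        f_cols = [np.ones(k)]
        if sd is not None:
            f_cols.append(sd[idx])
        F = np.stack(f_cols, axis=1)
        m = F.shape[1]
        A = np.zeros((k + m, k + m))
        A[:k, :k] = C
        A[:k, k:] = F
        A[k:, :k] = F.T

        dt = np.sqrt(((tgt[rows][:, None, :] - p[None, :, :]) ** 2).sum(-1))
        B = np.zeros((k + m, len(rows)))
        B[:k] = variogram.covariance(dt).T
        B[k] = 1.0
        if td is not None:
            B[k + 1] = td[rows]
        try:
            W = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            W = np.linalg.lstsq(A, B, rcond=None)[0]
        out[rows] = W[:k].T @ z[idx]
    return out


def downscale_field(
    coarse_values: np.ndarray,
    coarse_points: np.ndarray,
    target_points: np.ndarray,
    *,
    elevation_source: np.ndarray | None = None,
    elevation_target: np.ndarray | None = None,
    cutoff_km: float = 100.0,
    n_neighbours: int = 30,
) -> np.ndarray:
    """Fit a variogram to one monthly coarse field and krige it down."""
    vf = fit_variogram(coarse_points, coarse_values, cutoff_km)
    return krige(
        coarse_points,
        coarse_values,
        target_points,
        vf,
        source_drift=elevation_source,
        target_drift=elevation_target,
        n_neighbours=n_neighbours,
    )


# ---------------------------------------------------------------------
# derived surfaces
# ---------------------------------------------------------------------


def sunshine_fraction(sun_hours_month, northing_km, month: int) -> np.ndarray:
    """Convert monthly sunshine hours to the cloud-free fraction of daylight.

    Divides by day length x days in the month and clips to [0, 1];
    totals exceeding the astronomical maximum are clipped with a warning.
    """
    hours = np.asarray(sun_hours_month, dtype=float)
    if np.any(hours < 0):
        raise ValueError("sunshine hours must be non-negative")
    daylen = day_length_hours(month, northing_km=northing_km)
    maximum = daylen * DAYS_IN_MONTH[month - 1]
    frac = hours / maximum
    if np.any(frac > 1 + 1e-9):
        warnings.warn("sunshine hours exceed day length; clipping fraction to 1")
    return np.clip(frac, 0.0, 1.0)


def adjust_tmax_solar(tmin, tmax, solar_ratio) -> np.ndarray:
    """Rescale the diurnal temperature range by the topographic solar ratio.

    ``T_MaxSR = T_Min + ratio * (T_Max - T_Min)`` elementwise, with
    ratio = SR_topo / SR_flat supplied as an input raster.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("T_Max below T_Min")
    return tmin + np.asarray(solar_ratio, dtype=float) * (tmax - tmin)


def thornthwaite_pet(tmean_monthly: np.ndarray, northing_km=REF_NORTHING_KM) -> np.ndarray:
    """Monthly potential evapotranspiration (mm), Thornthwaite method.

    ``tmean_monthly`` stacks 12 monthly mean temperatures along axis 0
    in cycle order starting in September (the heat index is computed
    from the same 12 months).  Temperature-only by construction, which
    matches the inputs the pipeline has; documented as swappable.
    """
    t = np.asarray(tmean_monthly, dtype=float)
    if t.shape[0] != 12:
        raise ValueError("need 12 monthly mean temperatures")
    tp = np.clip(t, 0, None)
    I = ((tp / 5.0) ** 1.514).sum(axis=0)
    a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239
    months = [(m - 1) % 12 + 1 for m in range(9, 21)]  # Sep..Aug calendar months
    pet = np.zeros_like(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, m in enumerate(months):
            L = day_length_hours(m, northing_km=northing_km)
            N = DAYS_IN_MONTH[m - 1]
            val = 16.0 * (L / 12.0) * (N / 30.0) * np.where(I > 0, (10.0 * tp[i] / np.where(I > 0, I, 1.0)) ** a, 0.0)
            pet[i] = np.where(tp[i] > 0, val, 0.0)
    return pet


@dataclass
class AnnualClimate:
    """The three annual bioclimatic variables for one September-anchored year."""

    year_label: str  # e.g. "1976-77" for Sep 1976 - Aug 1977
    winter_min: np.ndarray  # deg C
    degree_days: np.ndarray  # deg C * day above 5 deg C
    moisture: np.ndarray  # annual rain / annual PET


_CYCLE_MONTHS = [(0, m) for m in range(9, 13)] + [(1, m) for m in range(1, 9)]


def annual_variables(
    tmin_monthly: dict[tuple[int, int], np.ndarray],
    tmaxsr_monthly: dict[tuple[int, int], np.ndarray],
    rain_monthly: dict[tuple[int, int], np.ndarray],
    start_year: int,
    northing_km=REF_NORTHING_KM,
) -> AnnualClimate:
    """Accumulate one September-anchored annual cycle of monthly surfaces.

    Inputs are dicts keyed by calendar ``(year, month)`` and must cover
    September ``start_year`` through August ``start_year + 1``; a
    missing month raises an error naming it.  Mean temperature is
    ``(T_Min + T_MaxSR) / 2``; winter minimum is the cycle minimum of
    monthly T_Min; degree-days use the monthly rectangle approximation
    ``sum max(0, T_Mean - 5) * days``; moisture balance is total rain
    over total Thornthwaite PET.
    """
    keys = [(start_year + dy, m) for dy, m in _CYCLE_MONTHS]
    for source, name in ((tmin_monthly, "T_Min"), (tmaxsr_monthly, "T_MaxSR"), (rain_monthly, "rain")):
        for key in keys:
            if key not in source:
                raise ValueError(f"missing {name} surface for {key[0]}-{key[1]:02d}")

    tmin = np.stack([np.asarray(tmin_monthly[k], dtype=float) for k in keys])
    tmaxsr = np.stack([np.asarray(tmaxsr_monthly[k], dtype=float) for k in keys])
    rain = np.stack([np.asarray(rain_monthly[k], dtype=float) for k in keys])

    tmean = 0.5 * (tmin + tmaxsr)
    days = np.array([DAYS_IN_MONTH[m - 1] for _, m in keys], dtype=float)
    shape = (12,) + (1,) * (tmean.ndim - 1)
    degree_days = (np.clip(tmean - 5.0, 0, None) * days.reshape(shape)).sum(axis=0)
    winter_min = tmin.min(axis=0)
    pet_total = thornthwaite_pet(tmean, northing_km=northing_km).sum(axis=0)
    moisture = rain.sum(axis=0) / np.maximum(pet_total, 1e-9)
    return AnnualClimate(
        year_label=f"{start_year}-{(start_year + 1) % 100:02d}",
        winter_min=winter_min,
        degree_days=degree_days,
        moisture=moisture,
    )
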
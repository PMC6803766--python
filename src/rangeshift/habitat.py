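"""Habitat-climate occurrence models and range-margin conditions.

For each species, presence records at 1-ha precision are combined with
weighted pseudo-absences — pixels visited under the same recording
scheme, near target presences, in landscapes occupied in both recording
periods, inside the species' flight period, and down-weighted by the
probability that presence would have been detected given the number of
visits.  A quasibinomial (binomial-logit, Pearson-dispersion)
regression on the 18 land-cover classes and three centred annual
climate variables yields the species' probability of occurrence per
habitat class; from this follow habitat specialisation (coefficient of
variation across the 18 probabilities), habitat availability at the
range margin (mean predicted suitability over a 50-km buffer on the
margin hectads) and exposure to climate change (logged ratio of mean
margin suitability under period-2 vs period-1 climate, habitat fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.special import expit
from scipy.stats import gaussian_kde

from rangeshift.grids import HA_KM, LC_PER_HA, GridSpec
from rangeshift.synthetic import N_CLASSES, PERIOD1, PERIOD2, LandCoverMap

CLIMATE_VARS = ("winter_min", "degree_days", "moisture")


# ---------------------------------------------------------------------
# pixel-level habitat assignment
# ---------------------------------------------------------------------


def assign_pixel_habitat(
    ha_iy: int, ha_ix: int, landcover: LandCoverMap
) -> tuple[int, float]:
    """Majority land-cover class and fraction weight for a 1-ha pixel.

    The 1-ha pixel spans a 4 x 4 block of 25 m pixels; the modal class
    is assigned with weight = modal count / 16.  Ties break to the
    lowest class code.  A pixel entirely of the discarded source class
    returns ``(-1, 0.0)`` and is excluded by callers.
    """
    block = landcover.classes[
        ha_iy * LC_PER_HA : (ha_iy + 1) * LC_PER_HA,
        ha_ix * LC_PER_HA : (ha_ix + 1) * LC_PER_HA,
    ].ravel()
    valid = block[block >= 0]
    if valid.size == 0:
        return -1, 0.0
    counts = np.bincount(valid, minlength=N_CLASSES)
    cls = int(counts.argmax())  # argmax takes the lowest index on ties
    return cls, counts[cls] / block.size


# ---------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------


def _pixel_key(easting, northing, grid: GridSpec):
    iy, ix = grid.ha_of_point(np.asarray(easting), np.asarray(northing))
    return iy * grid.ha_shape[1] + ix


def candidate_absences(
    species: str,
    scheme: str,
    visits: pd.DataFrame,
    records: pd.DataFrame,
    grid: GridSpec,
    radius_km: float = 50.0,
    periods=(PERIOD1, PERIOD2),
) -> pd.DataFrame:
    """Candidate pseudo-absence pixels for one species, with filter flags.

    Candidates are the 1-ha pixels visited under the species' recording
    scheme.  Flags mark pixels that fail each control: ``presence_pixel``
    (the species was recorded there — those are presences, not
    absences), ``too_far`` (no target presence within ``radius_km``),
    and ``single_period`` (the surrounding landscape holds target
    presences in exactly one recording period).  ``survives`` is True
    when no flag is set.  Visit counts ``t`` and visit dates are carried
    for the detection weight and phenology filter.
    """
    v = visits[visits["scheme"] == scheme].copy()
    if len(v) == 0:
        return pd.DataFrame(
            columns=["easting_km", "northing_km", "t", "dates", "presence_pixel", "too_far", "single_period", "survives"]
        )
    v["pixel"] = _pixel_key(v["easting_km"], v["northing_km"], grid)
    agg = v.groupby("pixel").agg(
        easting_km=("easting_km", "first"),
        northing_km=("northing_km", "first"),
        t=("date", "size"),
        dates=("date", lambda s: list(s)),
    )

    pres = records[(records["species"] == species) & (records["precision"] == "ha")].copy()
    cand = agg.reset_index()
    if len(pres) == 0:
        cand["presence_pixel"] = False
        cand["too_far"] = True
        cand["single_period"] = True
    else:
        pres["pixel"] = _pixel_key(pres["easting_km"], pres["northing_km"], grid)
        pres_pixels = set(pres["pixel"])
        cand["presence_pixel"] = cand["pixel"].isin(pres_pixels)

        xy_cand = cand[["easting_km", "northing_km"]].to_numpy()
        xy_pres = pres[["easting_km", "northing_km"]].drop_duplicates().to_numpy()
        tree = cKDTree(xy_pres)
        dist, _ = tree.query(xy_cand)
        cand["too_far"] = dist > radius_km

        years = pd.to_datetime(pres["date"]).dt.year
        in_p = [
            pres[(years >= p[0]) & (years <= p[1])][["easting_km", "northing_km"]]
            .drop_duplicates()
            .to_numpy()
            for p in periods
        ]
        near = []
        for arr in in_p:
            if len(arr) == 0:
                near.append(np.zeros(len(cand), dtype=bool))
            else:
                d, _ = cKDTree(arr).query(xy_cand)
                near.append(d <= radius_km)
        n_periods_near = np.sum(near, axis=0)
        cand["single_period"] = n_periods_near == 1

    cand["survives"] = ~(cand["presence_pixel"] | cand["too_far"] | cand["single_period"])
    return cand.drop(columns=["pixel"])


def _day_of_year(dates) -> np.ndarray:
    return pd.to_datetime(pd.Series(dates)).dt.dayofyear.to_numpy()


def phenology_keep(
    visit_days: np.ndarray,
    target_days: np.ndarray,
    tail: float = 0.10,
    min_dates_for_kde: int = 10,
) -> np.ndarray:
    """Keep-mask for visit dates inside the target's flight season.

    A kernel density (Silverman bandwidth) is fitted to the target's
    local record dates on a circularly shifted day-of-year axis (so
    winter-emerging species spanning the year break are handled); visit
    days in the lower or upper ``tail`` of the cumulative density are
    dropped.  With fewer than ``min_dates_for_kde`` dates, or a singular
    density, the tails come directly from the raw-date percentiles.
    """
    visit_days = np.asarray(visit_days, dtype=float)
    target_days = np.asarray(target_days, dtype=float)
    if target_days.size == 0:
        return np.zeros(visit_days.size, dtype=bool)

    # circular shift: centre the flight season mid-axis
    ang = 2 * np.pi * target_days / 365.0
    mean_day = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * 365.0 / (2 * np.pi)) % 365.0
    offset = (mean_day - 182.5) % 365.0
    t_shift = (target_days - offset) % 365.0
    v_shift = (visit_days - offset) % 365.0

    lo = hi = None
    if target_days.size >= min_dates_for_kde and np.ptp(t_shift) > 0:
        try:
            kde = gaussian_kde(t_shift)
            xs = np.linspace(0, 365, 1462)
            dens = kde(xs)
            cdf = np.cumsum(dens)
            cdf /= cdf[-1]
            lo = xs[np.searchsorted(cdf, tail)]
            hi = xs[np.searchsorted(cdf, 1 - tail)]
        except np.linalg.LinAlgError:
            pass
    if lo is None:
        lo, hi = np.percentile(t_shift, [100 * tail, 100 * (1 - tail)])
    return (v_shift >= lo) & (v_shift <= hi)


def phenology_filter(
    candidates: pd.DataFrame,
    records: pd.DataFrame,
    species: str,
    grid: GridSpec,
    radius_km: float = 50.0,
    tail: float = 0.10,
) -> pd.DataFrame:
    """Apply the phenology control to candidate absences.

    For each candidate pixel, target record dates within ``radius_km``
    define a local flight-season density; candidate visit dates in its
    tails are dropped.  A candidate with no surviving visit dates — or
    no local target dates at all (``no_phenology``) — stops being a
    usable absence (``survives`` set False); ``t`` is updated to the
    number of surviving visits.
    """
    pres = records[(records["species"] == species) & (records["precision"] == "ha")]
    out = candidates.copy()
    out["no_phenology"] = False
    if len(out) == 0:
        return out
    xy_pres = pres[["easting_km", "northing_km"]].to_numpy()
    pres_days = _day_of_year(pres["date"]) if len(pres) else np.array([])
    tree = cKDTree(xy_pres) if len(pres) else None

    new_t = out["t"].to_numpy().copy()
    new_dates = []
    no_phen = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples()):
        if tree is None:
            no_phen[i] = True
            new_t[i] = 0
            new_dates.append([])
            continue
        nearby = tree.query_ball_point([row.easting_km, row.northing_km], radius_km)
        if len(nearby) == 0:
            no_phen[i] = True
            new_t[i] = 0
            new_dates.append([])
            continue
        local_days = pres_days[nearby]
        vdays = _day_of_year(row.dates)
        keep = phenology_keep(vdays, local_days, tail=tail)
        new_t[i] = int(keep.sum())
        new_dates.append([d for d, k in zip(row.dates, keep) if k])
    out["no_phenology"] = no_phen
    out["t"] = new_t
    out["dates"] = new_dates
    out["survives"] = out["survives"] & ~out["no_phenology"] & (out["t"] > 0)
    return out


def detection_weight(t: int, presence_site_probs: np.ndarray) -> float:
    """Probability of recording the species in ``t`` visits if present.

    ``presence_site_probs`` are per-site detection frequencies p_s
    (records at site s / visits to site s) across the n known presence
    sites within the local landscape; the weight is
    ``(1/n) * sum_s [1 - (1 - p_s)^t]`` — one minus the probability of
    failing to detect the species on every occasion, averaged over
    presence sites.
    """
    if t < 1:
        raise ValueError("a candidate absence must have at least one visit")
    p = np.asarray(presence_site_probs, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one presence site")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    return float(np.mean(1.0 - (1.0 - p) ** t))


def detection_weights_for_absences(
    absences: pd.DataFrame,
    species: str,
    scheme: str,
    visits: pd.DataFrame,
    records: pd.DataFrame,
    grid: GridSpec,
    radius_km: float = 50.0,
) -> np.ndarray:
    """Detection weight per surviving absence pixel.

    Per-site detection probabilities p_s are record counts over visit
    counts at each presence site, restricted to presence sites within
    ``radius_km`` of the absence pixel to respect spatial variation in
    abundance.
    """
    v = visits[visits["scheme"] == scheme].copy()
    v["pixel"] = _pixel_key(v["easting_km"], v["northing_km"], grid)
    visits_per_pixel = v.groupby("pixel").size()

    pres = records[(records["species"] == species) & (records["precision"] == "ha")].copy()
    pres["pixel"] = _pixel_key(pres["easting_km"], pres["northing_km"], grid)
    recs_per_pixel = pres.groupby("pixel").size()

    sites = []
    for pix, n_rec in recs_per_pixel.items():
        n_vis = visits_per_pixel.get(pix, 0)
        if n_vis > 0:
            row = pres[pres["pixel"] == pix].iloc[0]
            sites.append((row["easting_km"], row["northing_km"], min(1.0, n_rec / n_vis)))
    if not sites:
        raise ValueError("no visited presence sites to estimate detection from")
    xy = np.array([(s[0], s[1]) for s in sites])
    ps = np.array([s[2] for s in sites])
    tree = cKDTree(xy)

    out = np.empty(len(absences))
    for i, row in enumerate(absences.itertuples()):
        idx = tree.query_ball_point([row.easting_km, row.northing_km], radius_km)
        if len(idx) == 0:
            idx = [int(tree.query([row.easting_km, row.northing_km])[1])]
        out[i] = detection_weight(int(row.t), ps[idx])
    return out


# ---------------------------------------------------------------------
# the occurrence model
# ---------------------------------------------------------------------


@dataclass
class SpeciesHabitatModel:
    """Fitted quasibinomial habitat-climate occurrence model."""

    species: str
    intercept: float
    class_coefs: np.ndarray  # length 18; reference class coded 0
    climate_coefs: np.ndarray  # length 3, on centred covariates
    climate_means: np.ndarray  # centring constants
    dispersion: float  # Pearson chi^2 / df
    class_probs: np.ndarray  # length 18, at centred climate
    reference_class: int
    flags: list[str] = field(default_factory=list)
    n_presence: int = 0
    n_absence: int = 0

    def predict_class_probs(self, climate: np.ndarray | None = None) -> np.ndarray:
        """Occurrence probability per habitat class at given climate values.

        ``climate`` is on the natural scale (centred internally); None
        means centred (mean) climate.
        """
        offset = 0.0
        if climate is not None:
            offset = float((np.asarray(climate, dtype=float) - self.climate_means) @ self.climate_coefs)
        return expit(self.intercept + self.class_coefs + offset)


def fit_habitat_model(data: pd.DataFrame, species: str = "") -> SpeciesHabitatModel:
    """Fit the per-species quasibinomial occurrence regression.

    ``data`` holds one row per presence/absence observation with columns
    ``y`` (1 presence / 0 absence), ``habitat_class`` (0..17),
    ``habitat_weight`` (majority-class fraction of the 1-ha pixel),
    ``detection_weight`` (1 for presences) and the three climate
    covariates ``winter_min``, ``degree_days``, ``moisture`` matched to
    the record year (multi-year pixels pre-averaged by the caller).

    The model is a binomial-logit GLM on the 18-class categorical and
    the centred climate covariates, with observation weight =
    habitat-fraction x detection weight; the quasibinomial dispersion is
    the Pearson chi-square over residual df and scales standard errors
    only.  Classes absent from the data get the intercept-only
    probability and are flagged; complete separation triggers a
    ridge-stabilised refit, flagged.
    """
    y = data["y"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("need both presences and absences to fit")
    classes = data["habitat_class"].to_numpy(dtype=int)
    if np.any((classes < 0) | (classes >= N_CLASSES)):
        raise ValueError("habitat classes must be 0..17 (discarded pixels excluded)")
    weights = data["habitat_weight"].to_numpy(dtype=float) * np.where(
        y == 1, 1.0, data["detection_weight"].to_numpy(dtype=float)
    )

    climate = data[list(CLIMATE_VARS)].to_numpy(dtype=float)
    climate_means = climate.mean(axis=0)
    zc = climate - climate_means

    observed = np.unique(classes)
    reference = int(observed.min())
    flags = [f"class-{k}-unobserved" for k in range(N_CLASSES) if k not in observed]

    cols = [np.ones(len(y))]
    contrast_classes = [k for k in observed if k != reference]
    for k in contrast_classes:
        cols.append((classes == k).astype(float))
    cols.append(zc)
    X = np.column_stack(cols)

    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=weights)
    ridge = False
    try:
        res = model.fit(maxiter=200)
        params = res.params
        if not np.all(np.isfinite(params)) or np.max(np.abs(params[: 1 + len(contrast_classes)])) > 12:
            ridge = True
    except Exception:
        ridge = True
    if ridge:
        res = model.fit_regularized(alpha=1e-3, L1_wt=0.0, maxiter=500)
        params = np.asarray(res.params)
        flags.append("ridge")

    mu = expit(X @ params)
    df_resid = max(len(y) - X.shape[1], 1)
    pearson = float(np.sum(weights * (y - mu) ** 2 / np.clip(mu * (1 - mu), 1e-12, None)))
    dispersion = pearson / df_resid

    intercept = float(params[0])
    class_coefs = np.zeros(N_CLASSES)
    for j, k in enumerate(contrast_classes):
        class_coefs[k] = params[1 + j]
    climate_coefs = np.asarray(params[-3:], dtype=float)

    probs = expit(intercept + class_coefs)  # centred climate: offset 0

    return SpeciesHabitatModel(
        species=species,
        intercept=intercept,
        class_coefs=class_coefs,
        climate_coefs=climate_coefs,
        climate_means=climate_means,
        dispersion=dispersion,
        class_probs=probs,
        reference_class=reference,
        flags=flags,
        n_presence=int((y == 1).sum()),
        n_absence=int((y == 0).sum()),
    )


def specialisation(class_probs: np.ndarray) -> float:
    """Habitat specialisation: CV (sample SD / mean) of the 18 class probabilities."""
    p = np.asarray(class_probs, dtype=float)
    if p.mean() <= 0:
        raise ValueError("class probabilities must have positive mean")
    return float(p.std(ddof=1) / p.mean())


# ---------------------------------------------------------------------
# range-margin conditions
# ---------------------------------------------------------------------


@dataclass
class MarginContext:
    """Habitat availability, specialisation and climate exposure at the margin."""

    species: str
    availability: float  # mean suitability over the buffer, centred climate
    log10_availability: float
    exposure: float  # ln(mean suitability p2 climate / p1 climate)
    specialisation: float
    n_buffer_pixels: int
    class_fractions: np.ndarray  # land-cover composition of the buffer


def buffer_class_fractions(
    landcover: LandCoverMap,
    grid: GridSpec,
    margin_centres: np.ndarray,
    radius_km: float = 50.0,
) -> tuple[np.ndarray, int]:
    """Class composition of the union of circles around margin hectads.

    ``margin_centres`` rows are (northing, easting) of margin-hectad
    centres.  Returns (length-18 fractions over valid buffer pixels,
    number of valid pixels).  Works at the 25 m grain.
    """
    centres = np.atleast_2d(np.asarray(margin_centres, dtype=float))
    ny, nx = landcover.classes.shape
    pix_n = grid.origin_northing_km + (np.arange(ny) + 0.5) * (HA_KM / LC_PER_HA)
    pix_e = grid.origin_easting_km + (np.arange(nx) + 0.5) * (HA_KM / LC_PER_HA)
    mask = np.zeros((ny, nx), dtype=bool)
    r2 = radius_km**2
    for cn, ce in centres:
        dn2 = (pix_n - cn) ** 2
        de2 = (pix_e - ce) ** 2
        mask |= dn2[:, None] + de2[None, :] <= r2
    sel = landcover.classes[mask]
    sel = sel[sel >= 0]
    if sel.size == 0:
        raise ValueError("empty range-margin buffer")
    return np.bincount(sel, minlength=N_CLASSES) / sel.size, int(sel.size)


def margin_context(
    model: SpeciesHabitatModel,
    landcover: LandCoverMap,
    grid: GridSpec,
    margin_centres: np.ndarray,
    climate_p1: np.ndarray,
    climate_p2: np.ndarray,
    radius_km: float = 50.0,
) -> MarginContext:
    """Range-margin habitat availability and climate-change exposure.

    Availability is the buffer-wide mean of the model's predicted
    suitability with climate at centred values (equivalently the
    class-composition-weighted mean of the 18 class probabilities, which
    matches the pixel-by-pixel mean exactly because suitability depends
    on a pixel only through its class).  Exposure is the natural-log
    ratio of mean buffer suitability with climate set to the period-2
    vs period-1 means, habitat held fixed; swapping the periods negates
    it.
    """
    frac, n_pix = buffer_class_fractions(landcover, grid, margin_centres, radius_km)
    p_centred = model.predict_class_probs()
    availability = float(frac @ p_centred)
    suit1 = float(frac @ model.predict_class_probs(climate_p1))
    suit2 = float(frac @ model.predict_class_probs(climate_p2))
    return MarginContext(
        species=model.species,
        availability=availability,
        log10_availability=float(np.log10(availability)),
        exposure=float(np.log(suit2 / suit1)),
        specialisation=specialisation(model.class_probs),
        n_buffer_pixels=n_pix,
        class_fractions=frac,
    )
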
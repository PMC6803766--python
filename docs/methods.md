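# Methods

This note records the models the package implements, the choices made
where the method leaves room, and what the synthetic-data generator
does and does not emulate.

## Geometry and units

All coordinates are planar kilometres (easting, northing) on a
national-grid-like plane; "latitude" always means planar northing, so
shifts are reported directly in km. Three nested grains: hectads
(10 km), focal pixels (1 ha = 100 m), and land-cover pixels (25 m);
every finer pixel nests in exactly one coarser cell. A nominal
geographic anchor (54° N at northing 500 km, 111.32 km per degree)
converts northing to latitude where day length is needed. Rasters are
exchanged as single-band ESRI ASCII grids (text), record and visit
tables as CSV with ISO-8601 dates.

## Recording periods

Two 15-year periods, 1976–1990 and 2001–2015; midpoints 25 years
apart. Records are assigned to periods by calendar year; records
outside both periods still contribute to regional species pools (pools
use all records of a group, deliberately ignoring the other inclusion
criteria).

## Effort control

The regional pool of a hectad is the distinct species of a group
recorded across its nearest 100 hectads by centroid distance. The
focal hectad is included (99 neighbours + self) and distance ties break
by hectad id, making pools deterministic and identical for identical
neighbourhoods; regions smaller than 100 hectads use all hectads with
a warning. A hectad is well recorded when its recorded richness
reaches the threshold fraction of the pool (≥, boundary inclusive) in
*both* periods and at least one species was recorded; 10% is the
analysis threshold, 25% defines the recording-intensity metric
(count of qualifying hectads).

Species inclusion requires: ≥ 90% of first-period occupied hectads in
the warmest half of the region (hectads ranked by first-period mean
annual temperature — the criterion is anchored to the historical
distribution, so period-1 temperature is used); no first-period record
within 100 km of the northern boundary; ≥ 20 occupied well-recorded
hectads in both periods; ≥ 200 distinct 1-ha presence pixels.
Non-native/vagrant/extinct status are input flags (they derive from
external registers, not from the records). Verdicts carry
machine-readable reason codes.

## Margins and rates

The margin is the mean northing of the ten northernmost occupied
well-recorded hectad centres; all hectads tied with the 10th-highest
northing are included. Hectad northing means the cell centre — the
constant 5-km offset cancels in differences. The expansion-room check
requires ≥ 10 well-recorded hectads within 100 km strictly north *and*
strictly south of the first-period margin.

Annualisation samples one uniform calendar day from each period
(leap days included), measures the interval in days/365.25, and
divides. The per-species summary is the median of 10,000 resampled
rates; by the symmetry of the two equal-length periods the median
interval is 25 y. Cross-species summaries are computed per resampled
interval; the CI is the 2.5/97.5 percentile band of those
per-interval summaries, and the headline statistic is the mean (the
median is reported alongside).

## Climate downscaling

Per month and variable, an empirical semivariogram is binned into 15
equal-width bins to a 100-km cutoff; spherical and exponential models
(nugget, partial sill, range; exponential in the practical-range
convention γ = c(1 − e^{−3h/r})) are fitted by bounded least squares
and the lower unweighted SSE wins. Variograms are fitted per month ×
variable rather than pooled. A constant field yields a flagged
pure-nugget fit (sill 0) and kriging then returns the constant.

Kriging solves the covariance-form system on the nearest 30 source
points, with unbiasedness constraints spanning {1} (ordinary; rain,
sunshine) or {1, elevation} (universal; temperatures). The constraints
make any drift-linear noiseless field exact, and a zero nugget makes
the interpolator honour source values exactly. Targets sharing a
neighbour set share one factorisation. The nugget defaults to a free
parameter but synthetic tests use 0 to preserve exactness.

Sunshine hours divide by day length × days-in-month (standard solar
declination/hour-angle day length at the pixel's nominal latitude,
mid-month day) and clip to [0, 1], warning when input exceeds the
astronomical maximum. T_MaxSR = T_Min + ratio × (T_Max − T_Min) with
the SR_topo/SR_flat ratio supplied as an input raster (computing it
from slope/aspect/hillshade is out of scope). T_Mean =
(T_Min + T_MaxSR)/2.

Annual variables accumulate over 12-month cycles starting 1 September
(the biologically coherent year; the annual temperature minimum then
falls inside the cycle, which is how "minimum winter temperature" is
defined here: the cycle minimum of monthly T_Min). Degree-days use the
monthly rectangle approximation Σ max(0, T_Mean − 5 °C) × days — only
monthly grids exist, so no daily interpolation is attempted; this
under-counts months straddling the threshold. PET is Thornthwaite's
monthly formula from T_Mean and day length — chosen because it is the
only standard formula whose inputs the pipeline has; the moisture
balance is annual rain over annual PET and the PET implementation is a
single swappable function.

## Habitat-climate occurrence models

A 1-ha observation takes the majority class of its 16 land-cover
pixels with weight = modal count/16 (ties to the lowest class code;
pixels wholly of the discarded source class are excluded). Climate
covariates are matched to the observation year (multi-year pixels
averaged) and centred on the means over the species' model-fitting
observations.

Pseudo-absences are pixels visited under the species' own recording
scheme (visitation is deduced from the scheme's visit table), within
50 km of a target presence, excluding landscapes — 50-km
neighbourhoods, matching every other radius in the analysis — where
the target was present in exactly one period. The phenology filter
fits a Gaussian KDE (Silverman bandwidth) to target record
days-of-year within 50 km of the candidate, on a circularly shifted
axis centred on the circular mean date so winter-emerging species
spanning the year break are handled; visit dates in the lower/upper
10% of the cumulative density are dropped, with raw 10th/90th
percentiles as the fallback below 10 dates or on a singular density.
Remaining absences are weighted by (1/n) Σₛ [1 − (1 − pₛ)ᵗ] with
pₛ = records/visits at each presence site within 50 km and t the
pixel's surviving visit count.

The regression is a binomial-logit GLM (statsmodels) on the 18-class
categorical plus the three centred climate covariates; the
quasibinomial dispersion is Pearson χ²/df and scales uncertainty only,
leaving point estimates untouched. Observation weight is the product
of the habitat-fraction weight and (for absences) the detection
weight — the method lists both without a combination rule, and the
product is the natural choice for independent down-weightings;
presences carry habitat-fraction weights only. Unobserved classes get
the intercept-only probability and a flag; complete separation
(detected as non-convergence or |class coefficient| > 12) triggers a
flagged ridge-stabilised refit (L2, α = 1e-3).

Class probabilities at centred climate give specialisation =
CV = sample SD (n−1) / mean — the (n−1) convention matches common
usage of the index and is a one-line switch. Availability is the mean
predicted suitability over all valid 25-m pixels in the union of
50-km circles around the first-period margin-hectad centres; because
suitability depends on a pixel only through its class, this is
computed exactly as the class-composition-weighted mean of the 18
probabilities. Availability is reported raw and log₁₀-transformed.
Exposure is the *natural* log of the ratio of mean buffer suitability
under period-2 vs period-1 mean climate (log₁₀ is reserved for
availability, where the method specifies it); the base only rescales
regression slopes, and the log makes exposure antisymmetric about no
change.

## Mixed models of range shift

The response is the per-species median annual rate; fixed effects are
log₁₀ availability, specialisation, exposure and the
availability × exposure interaction (never specialisation and
availability together: pairwise |r| ≥ 0.5 is the configurable
exclusion rule); taxonomic group is a random intercept absorbing both
relatedness and recording-scheme differences. Predictors enter on
their natural scales; nothing is standardised.

Estimation is REML with the variance ratio λ = σ²_g/σ²_e profiled on
the log scale (bounded scalar minimisation, tolerance ~1e-8 on λ);
boundary estimates report σ²_g = 0 with a flag and the fit degenerates
to OLS, as it also does with a single group. All downstream statistics
come from closed group-block forms:

- **Satterthwaite tests**: df = 2g²/(∇g′A∇g), with g(θ) the
  coefficient's sampling variance, ∇g by central finite differences in
  (σ²_g, σ²_e), and A twice the inverse finite-difference Hessian of
  the −2·REML log-likelihood; df is capped at the residual n − p and
  falls back to it at boundary fits.
- **R²**: R²m = var(Xβ)/(var(Xβ) + σ²_g + σ²_e), R²c adds σ²_g to the
  numerator (sample variance of the fixed-effect predictions).
- **Conditional AIC**: −2 × conditional log-likelihood (residuals
  about Xβ̂ + BLUPs, scale σ²_e) + 2(ρ + 1), where ρ is the trace of
  the hat matrix mapping y to the conditional fits — computed in
  closed form as p + Σ_g σ²_g n_g/(σ²_e + σ²_g n_g) − a p×p trace
  correction, and verified against the explicit n×n matrices in tests.
  As σ²_g → 0 this reduces to the fixed-effects-only AIC at the same
  residual variance.

The sensitivity sweep qualifies groups by recording intensity at each
threshold, draws 3 qualifying groups and 30 species per repetition
(fixing model degrees of freedom), refits the interaction model and
averages the interaction slope and R²m over repetitions; thresholds
with fewer than 3 qualifying groups are flagged and skipped. Tests use
hundreds of repetitions rather than the 10,000 of a full analysis; the
estimand is a mean over i.i.d. repetitions, so repetition count only
sets Monte-Carlo error.

## The synthetic world

The generator produces the three input streams with known truth:

- **Landscape**: 25-m land cover over the 18-class legend (an
  aggregation map from a 23-class source legend — one class discarded,
  14 kept, 8 merged into 4 — is provided for ingesting source-coded
  rasters). Classes are i.i.d. categorical draws at autocorrelation
  scale 0, otherwise the argmax of log mixing weights plus smoothed
  Gaussian fields (Gumbel-scaled), generated at the 1-ha grain and
  block-upsampled — patches are ≥ 1 km across, so sub-hectare noise
  would add nothing, at the cost that generated (not ingested) 1-ha
  pixels are single-class and habitat-fraction weights are exercised
  with hand-built rasters in tests. Elevation and the solar-radiation
  ratio (clipped to (0, 1.5]) are smoothed-noise 1-ha rasters.
- **Climate**: monthly 5-km grids, 1976–2015, with a fixed seasonal
  profile, a latitudinal gradient (−0.6 °C/100 km), a linear warming
  trend (0.032 °C/y — 0.8 °C across the 25-year midpoint gap, the
  warming level of the study region), an elevation lapse (−6 °C/km)
  and optional i.i.d. noise; mean annual temperature ~8.5 °C in the
  first period. Rain and sunshine follow fixed seasonal profiles with
  optional multiplicative noise; sunshine is capped by day length.
- **Species**: habitat-preference log-odds vectors with varying
  concentration (specialist → generalist), three climate-response
  coefficients (positive on accumulated warmth, so warming favours
  expansion), a southern baseline range, a dispersal radius (km/y),
  per-visit detectability and a flight window.
- **Occupancy**: one annual step; occupied hectads persist with
  probability equal to their mean suitability (inverse-logit of class
  preference + climate response, averaged over hectad composition);
  unoccupied hectads within the dispersal radius of an occupied one
  colonise with the same probability. This is the package's own
  minimal forward model — just enough structure for habitat- and
  climate-limited expansion with a recoverable margin signal.
- **Recording**: per-scheme Poisson visits per hectad-year (spatially
  scalable, or an exhaustive census), each to a uniform 1-ha pixel on
  a uniform day; a present species is recorded when the day falls in
  its flight window and a Bernoulli(detectability) succeeds. Records
  are therefore a subset of (occupied pixel, visit) pairs and the
  visit table is a superset of record events.

What the generator does *not* emulate: coastline and real geography,
spatially correlated recorder preferences (effort varies by hectad but
visits are uniform within), land-cover change over time, abundance
variation within occupied hectads (presence is hectad-wide),
observation-level taxonomic error, and temporal autocorrelation in
weather. Passing recovery tests therefore demonstrates the estimators
are correct and unbiased under a known, well-behaved generating
process — not that the real datasets satisfy these assumptions.

## Problem sizes and numerical conventions in the tests

Test worlds are 3 × 8 hectads (30 × 80 km) over the full 40-year span;
occurrence-model recovery uses 1,200–1,500 observations per fit;
cohort recoveries use 50–100 seeds; the sweep uses 400 repetitions at
3 thresholds; the mixed-model type-I simulation uses 400 null
datasets. These sizes put Monte-Carlo error comfortably inside the
asserted bounds while keeping the default suite under a minute of
compute. The variogram model-selection oracle samples its Gaussian
process on a regular 10-km grid — the sampling layout of the coarse
climate inputs — where the spherical/exponential contest is decided
reliably; scattered sparse samples genuinely cannot separate the two
models on single realisations.

Degenerate inputs are contracts, not surprises: margins need ≥ 10
hectads, kriging ≥ 2 sources, variograms ≥ 10 points, mixed models
more observations than fixed parameters, detection weights ≥ 1 visit
and ≥ 1 presence site; empty margin buffers and all-presence
regressions raise. Ties break deterministically everywhere (hectad id,
lowest class code), and every stochastic routine takes an explicit
seed or Generator.

## Known limitations

- Thornthwaite PET ignores radiation and wind; the moisture balance is
  only as good as that approximation (documented as swappable).
- The monthly rectangle degree-day sum underestimates accumulation in
  months whose daily mean crosses 5 °C.
- The quasibinomial dispersion scales uncertainty but the habitat
  model's spatial autocorrelation is otherwise unmodelled (as in the
  method it implements).
- Satterthwaite df and the REML information use finite differences;
  with near-boundary variance ratios the df fall back to n − p rather
  than attempting an ill-conditioned Hessian inverse.
- The sensitivity sweep assumes species are exchangeable within
  groups; it does not model within-group recording heterogeneity.
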
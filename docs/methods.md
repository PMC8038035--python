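# Methods

## Concentration-response model

The attribution chain is the standard short-term log-linear model used in
air-pollution health impact assessment (the same arithmetic as BenMAP or
AirQ+ for a single pollutant and endpoint):

1. **Impact function.** A relative risk RR quoted per reference increment
   X₀ (10 µg/m³ throughout) implies a risk multiplier IF(ΔX) = RR^(ΔX/X₀)
   at an arbitrary daily increment ΔX. IF(0) = 1 and IF is strictly
   increasing in ΔX when RR > 1.
2. **Attributable number.** AN = (IF − 1) × Pop × r, with Pop the district
   population (a census snapshot held constant over the episode — no
   demographic dynamics) and r the baseline incidence rate per person per
   day.
3. **Aggregation.** AN is additive, so district-day records are summed
   over any partition (per day, per district, or a grand total); the three
   aggregations are conserved to floating-point accuracy.

**Annual→daily rates.** Published incidence rates are annual; the model is
applied per day, so rates are divided by 365 (calendar days). The
alternative 365.25 differs by <0.1 %, far below the uncertainty of any RR;
the simpler convention is fixed and not configurable.

**Confidence bounds.** The low/high RR bounds are substituted through
steps 1–2 (plug-in propagation), matching how endpoint CI triples are
reported in the source epidemiology. This ignores correlation between
days and endpoints and is not a sampling-based interval; no Monte Carlo
is attempted. The ordering an_low ≤ an_central ≤ an_high is guaranteed
whenever ΔX ≥ 0 and the RR triple is ordered.

**Negative increments.** Modelled increments can be slightly negative
(numerical noise, background subtraction); the attribution model is
defined only for ΔX ≥ 0, so district means are clamped to zero *after*
zonal averaging.

**Default endpoints** (per 10 µg/m³): mortality RR 1.0123 (1.0045,
1.0201) and cardiovascular hospitalizations RR 1.0091 (1.0017, 1.0201)
from the WHO HRAPIE short-term recommendations; respiratory
hospitalizations RR 1.03 (1.01, 1.04) from a 2003 California wildfire
study. Same-day attribution only — distributed lags are out of scope.
Missing population or rate for a district is a hard error naming the
district; an explicit `fill="domain_mean"` policy substitutes the mean of
available districts.

## Exposure assignment (zonal statistics)

Grid cells are treated as rectangles carrying cell-averaged values (areal
semantics, not point samples); the grid origin is the outer corner of
cell (0, 0) and the row index increases away from the origin along y.
Two methods:

* `area_weighted` (default): mean of intersecting cell values weighted by
  exact polygon∩cell area, computed with shapely. Intersection pieces
  below 1e-9 of the district area are discarded as geometric noise.
  Districts are comparable in size to coastal 12 km cells, so weighting
  matters.
* `cell_center`: unweighted mean of cells whose centers fall strictly
  inside the polygon — faster, and an exact cross-check when district
  boundaries coincide with cell boundaries.

Missing cells (NaN) are excluded; the mean is over the covered area only
and a `coverage` fraction is reported, with a warning below 0.9. A
district intersecting no cell yields a missing value plus a warning, not
an error. Negative means are clamped afterwards (above).

## Rate projection between administrative layers

Hospitalization rates arrive on polygon layers that are not nested with
the exposure districts. Each target district receives the **unweighted
mean** of the rates of all source regions whose intersection exceeds
1e-6 of the target area (sliver threshold for digitization artifacts);
an `area_weighted_mean` variant is provided for sensitivity analysis.
The unweighted default mirrors the conventional "average of intersected
regions" phrasing of such analyses; whether real studies weight by area
is typically unstated, which is exactly why both are exposed behind one
flag. Rates are first averaged over a configurable year list (default
2014–2016) with a hard error on missing years unless
`fill="available_mean"`. The projected rate is always bounded by the
contributing rates, and identical tessellations project as the identity.

## Model evaluation statistics

* **R²** is the squared Pearson correlation of predicted vs observed —
  invariant to affine rescaling of either series, NaN (not 0) when either
  series is constant.
* **IOA** is Willmott's (1981) original squared-deviation form, the
  common default in air-quality model evaluation (not the modified |·| or
  refined dᵣ variants). It is 1 iff prediction equals observation and 0
  for, e.g., a constant prediction equal to the observed mean's
  reflection; it penalizes bias and is *not* affine-invariant. A zero
  denominator with imperfect agreement is impossible for this form
  (triangle inequality), so the undefined-statistic branch is defensive
  only.
* **Daily averaging** of hourly series requires ≥ 75 % valid hours per
  calendar day (configurable); incomplete days propagate as missing.
* **Grid-to-point matching** is the containing-cell value (no bilinear
  interpolation, keeping oracle tests exact); a point on a cell edge
  deterministically belongs to the lower-index cell.

## Synthetic world

The generator emulates the *structure* of a chemistry-transport
simulation of a severe fire season, not its physics:

* **Fields**: each fire source contributes, on each active day, an
  anisotropic Gaussian centred downwind of the source by that day's wind
  displacement (velocity × 86 400 s), elongated along-wind (default
  σ_along = 60 km, σ_cross = 25 km), with amplitude strength ×
  decay^(age). Cell value = background + Σ contributions. The default
  scenario — a 100×100 grid of 12 km cells, 30 days, six staggered
  coastal fire clusters of core strength 200–1500 µg/m³ with per-day
  decay 0.85–0.98, advected by an oscillating westerly of ~2–8 m/s —
  produces episodic multi-day peaks from tens to above 1000 µg/m³ over a
  mostly clean domain, the regime observed in severe fire seasons. There
  is no chemistry, deposition, or vertical structure; the fields exist to
  exercise overlay and attribution arithmetic with realistic magnitudes.
* **Layers**: jittered rectangular tessellations (cut-line jitter ±30 %
  of the regular spacing) — full coverage, no overlaps; the exposure
  layer (default 28 polygons, the size of a state's census-district
  partition) and the rate-region layer (default 60) are jittered
  independently, so they are non-nested like real administrative
  geographies.
* **Tables**: populations log-uniform in [10⁴, 10⁶] persons; annual rates
  uniform in [0.005, 0.01] (mortality) and [0.01, 0.05]
  (hospitalizations) per region, drawn per year with ±10 % year-to-year
  variation so multi-year averaging is exercised. Degenerate bands
  [r, r] force exact rates for closed-form tests.
* **Stations**: observed = containing-cell value × exp(ε),
  ε ~ N(0, σ), predicted = containing-cell value. σ = 0.3 by default.

All generators are pure functions of (parameters, seed).

**What a green test does and does not establish.** The synthetic world
has rectangular districts, multiplicative station noise independent in
time, no terrain or coastline masking, no anthropogenic background, and
plume kernels rather than dispersion physics. Green tests therefore
establish that the *arithmetic* — overlay weights, rate projection,
impact-function attribution, CI propagation, aggregation, and the
evaluation statistics — is correct against independent oracles and
closed forms; they say nothing about how well a real chemistry-transport
field or real administrative geographies would be reproduced, and the
published totals of any real episode are not reproducible without the
original (undeposited) model fields and health tables.

## Numerical choices

* Zonal and projection slivers: 1e-9 and 1e-6 of the reference area.
* Closed-form recovery asserted to 1e-6 relative; exact hand cases to
  1e-12; overlay-vs-oracle to 1e-9 absolute.
* CRS: a registry of named affine transforms (metre, kilometre, and
  equirectangular degrees about 34° S). This deliberately avoids a full
  projection library: the pipeline's native space is one projected CRS,
  and the registry keeps reprojection exactly invertible for tests.
  Datum-correct transforms of real shapefiles are out of scope.
* CSVs are UTF-8, comma-separated, ISO-8601 dates; re-runs at a fixed
  seed are byte-identical.

## Known limitations

Same-day attribution only (no lag structure); no age/sex stratification
or years-of-life-lost; population-weighted (dasymetric) exposure not
implemented; plug-in CI bounds understate combined uncertainty; the
synthetic generator cannot stand in for a validated dispersion model.
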
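# Methods

## The risk model

The package implements an environmental-matching ballast water risk
model. A port's environment is reduced to four climatological statistics
of sea-surface conditions — mean temperature of the warmest month
(T_max), mean temperature of the coldest month (T_min), annual mean
temperature (T_avg) and annual mean salinity (S) — z-scored over a
reference population of ports, and the risk of a tank discharge is an
inverse function of the Euclidean distance between the source and
destination vectors. The model's assumptions are those of environmental
matching generally: temperature and salinity are treated as the dominant
controls on survival and establishment of transported organisms,
propagule pressure enters only descriptively (tank counts per route),
and management actions such as mid-ocean exchange are deliberately not
modelled — the assessment is a precautionary worst case for the water as
taken up.

Distances are categorised into quintile risk classes. The default class
boundaries (0.787, 1.500, 2.778, 4.020) are the global calibration used
operationally for the annual-scale model; `percentile_thresholds`
recomputes boundaries as the 20/40/60/80th percentiles of any distance
collection (linear interpolation between order statistics, the default
of common statistical software). By default the same boundaries are
applied to monthly-scale distances, which the four-slot monthly vector
(below) makes scale-compatible.

## Monthly-scale vectors

How to build a *monthly* environmental vector inside a 4-component
annual model is genuinely open. The package's default keeps the 4-slot
geometry: for month *m*, the month's temperature fills T_max, T_min and
T_avg, and the month's salinity fills S. Two properties motivated this
choice: monthly and annual distances live on the same scale (so their
difference is meaningful), and for a port with no seasonality the
monthly vector *is* the annual vector, making the two assessments agree
exactly in that limit. A 2-component ⟨T, S⟩ mode
(`monthly_raw_vector(..., mode="two_component")`) is available for
sensitivity analysis but changes the distance scale and is not the
default.

Normalisation populations follow the same logic. Annual vectors are
z-scored against the reference ports' annual vectors; monthly vectors
are z-scored against the pooled port × month population (12 n vectors),
one shared scaling for all months so that within-year comparisons are
coherent. The z-score uses the sample (n−1) standard deviation
throughout. Because the pooled monthly fit sees each port's values 12
times, its standard deviation differs from the annual fit's by the
factor sqrt(12(n−1)/(12n−1)) even when every profile is month-constant —
a relative offset below one percent at realistic port counts. Where the
exact constant-limit equivalence matters, the pipeline option
`monthly_norm_source="annual"` reuses the annual normalisation for
monthly vectors, under which month-constant profiles give bit-identical
monthly and annual distances.

For tank records, the source vector is taken at the *uptake* month and
the destination vector at the *discharge* month: the dates on the
ballast water reporting form are exactly the times at which the water's
source community was sampled and released.

## Grid matching

Ports are matched to the climatology by great-circle distance, computed
with the haversine formula on a sphere of radius 6371 km; at one-degree
grid scale the difference from an ellipsoidal geodesic is far below the
grid spacing. Matching runs per layer (12 months × 2 variables): a
layer's missing cells are dropped and the nearest-cell search rerun, so
a month with a gap at the port's primary cell is served by the nearest
cell that does carry data — different months may legitimately use
different cells. Equidistant cells are broken deterministically by
lowest latitude, then lowest longitude.

Ports farther than `max_cells` (default 2) grid cells from usable data
are excluded; the cutoff is expressed in kilometres as cells × 111 km
(222 km at the default), with the boundary value kept (exclusion is
strictly greater-than). A port whose match exceeds the cutoff in *any*
layer is excluded overall — the stricter of the two possible readings,
chosen so that every retained profile has all 24 values and no
downstream stage needs gap handling.

## Temporal comparison

Per tank record, `diff = d_month − d_annual`; negative values mean the
monthly assessment sees the route as environmentally closer (riskier).
Differences are categorised against the 75th/90th percentiles of the
positive and the negative difference sets separately (defaults 0.835 /
1.586 and −1.720 / −2.248, the published calibration for Canadian
discharges; `diff_threshold_mode="data"` recalibrates from the run's own
differences). Zeros belong to neither side; boundary values join the
inner (75–90%) band; if one side of a calibration set is empty, that
side's categories are simply never assigned. Per-port summaries average
diffs over all tanks discharged at the port before categorising, so a
port is flagged only when its whole discharge mix shifts.

The regional test is the two-sided Wilcoxon signed-rank on the paired
(monthly, annual) distances, per destination region and year. Zero
differences are dropped before ranking (the classical signed-rank
convention); p-values use the exact null distribution when the nonzero
sample is ≤ 25 and tie-free, and the tie-corrected normal approximation
(no continuity correction) otherwise. The signed z statistic is always
computed from the rank sum, z = (W⁺ − n(n+1)/4) / σ with the tie-corrected
σ, so an effect size r = |z|/√N is available on both branches; its sign
is positive when monthly distances exceed annual ones. Magnitude labels
follow the convention of the standard effect-size tooling: r < 0.3
small, 0.3 ≤ r < 0.5 moderate, r ≥ 0.5 large. No multiple-testing
correction is applied across regions; the per-region tests are reported
side by side, as is usual for this kind of descriptive regional
comparison.

## Seasonal cycling

The tank-level comparison inherits the traffic's biases: heavily sailed
routes dominate, and each route is only observed in the months it
happened to be sailed. The standardised analysis removes both. Tank
records collapse to unique (source, destination) routes with a mean
voyage time τ (days, from the reported uptake and discharge dates);
for each route the departure is cycled over the 12 calendar months,
departing on the 1st (configurable to the 15th; the analysis cycles
months, so any fixed within-month anchor is defensible), arriving
round(τ) days later with calendar wrap-around, and the monthly-scale
distance is computed for each start month. The standard deviation of the
12 distances (sample, n−1, as everywhere in the package) measures the
route's within-year risk variability; routes at or above the cohort's
90th percentile are flagged, and their intersection with high-traffic
routes (default > 250 tanks) identifies the high-intensity /
high-variability corridors that deserve management attention.
Region-by-start-month curves average routes *unweighted* by tank count —
replicate-tank weighting is exactly the bias this analysis removes.

## Synthetic data

The generator produces the three pipeline inputs with the statistical
structure the analysis assumes. Temperature at latitude φ and month m is

    T(φ, m) = base(φ) + amp(φ) · cos(2π (m − peak)/12) + ε,

with base(φ) falling from 28 °C at the equator to −2 °C at the poles
(cos² profile), amplitude peaking at 8 °C in the temperate band
(Gaussian in |φ| around 45°, width 20°), peak month 7 in the northern
and month 1 in the southern hemisphere, and independent Gaussian noise
(sd 0.3 °C) per cell and month — the simplest model under which seasonal
structure dominates. Salinity is near-oceanic (34 ± a gentle latitudinal
gradient); an estuary fraction (15%) of ports gets a 3-unit depressed
mean and a 2.5-unit seasonal oscillation, imprinted on the port's
nearest grid cell. The one-degree grid is a single meridional ocean
basin with a land margin; 8% of source ports are placed deep inland to
exercise the exclusion rule, and 2% of ocean cells are masked at random
per layer. Traffic connects 48 source ports (five labelled regions
across both hemispheres) to 12 destination ports on three coasts
(Pacific/Atlantic/Arctic, the Arctic sparse); tanks-per-route counts are
Pareto-tailed (a few corridors carry most tanks), route voyage times are
uniform in 5–45 days, and discharges are uniform over the two assessment
years 2019–2020. Every generator is a pure function of the scenario
seed.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: real coastline geometry and
bathymetry, spatially correlated climatology errors, El Niño-type
interannual variability (the fields are one climatological year),
seasonally structured shipping schedules (synthetic discharge dates are
uniform through the year), and the actual magnitudes of real-world
calibrations, which depend on the true global port distribution. The
generator validates the *machinery* and its invariants (hemisphere
anti-phase, temperate-band variability, exclusion accounting, effect
recovery), not any particular published number.

For effect-recovery studies, `generate_paired_distances_with_shift`
draws paired distances whose differences are Gaussian with a location
shift chosen by `shift_for_target_r`, inverting the asymptotic relation
r = √3 (P(d_i + d_j > 0) − ½) for the signed-rank statistic; the
designed classes use the magnitude-band midpoints r = 0.15, 0.40, 0.70.

## Numerical choices

* Great-circle distances: haversine, radius 6371 km; ties broken by
  (lat, lon) lexicographic order.
* Annual means are computed with the shifted (provisional-means)
  formulation `x₀ + mean(x − x₀)`, numerically equivalent to the direct
  mean but exact for constant input, which makes the constant-seasonality
  equivalence between the two temporal scales bit-exact rather than
  approximate.
* Percentiles everywhere use linear interpolation between order
  statistics (numpy default).
* Standard deviations are sample (n−1) throughout: normalisation fits,
  per-port seasonal spread, cycled-distance spread.
* Longitudes are wrapped to [−180, 180) on load; in-range values pass
  through bit-identically so round trips are exact. CSV readers parse
  floats in round-trip mode for the same reason.
* Equal-interval binning spans [min, max] with the maximum closed into
  the top bin; a degenerate (constant) collection collapses to one bin.
* Loaders drop and report bad records (out-of-range coordinates,
  unparseable dates, unresolvable ports) but abort on structural defects
  (missing columns, fewer than 12 months); every stage's counts must
  reconcile (input = retained + excluded) in the run manifest.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
scenarios sized for desk-scale verification: the default world has 60
ports on a 141 × 41 one-degree grid with a few thousand tank records on
120 routes, property checks use 10⁴–10⁵ random draws, the matching
oracle scans 50 × 50 grids for 10³ ports, and recovery studies use 200
replicates of N = 500. These sizes make every property sharp (sampling
error well below the asserted tolerances) while keeping a full run in
seconds; the pipeline itself is vectorised per port and caches per-route
distances, and has no intrinsic scale limit beyond memory for the
distance-pair table.

## Known limitations

* The monthly-vector construction and its normalisation population are
  principled choices among several defensible ones; results at the
  monthly scale are conditional on them (the config switches expose the
  alternatives).
* Risk-class thresholds calibrated for annual distances are reused for
  monthly distances by default; a dedicated monthly calibration would
  shift class shares.
* Coast assignment of destination ports is taken as an input column, not
  derived from geography.
* The Wilcoxon implementation tests symmetry about zero of the paired
  differences; it does not model within-route dependence of tank
  records (tanks on the same voyage are not independent), which real
  reporting data exhibit strongly — effect sizes should be read
  descriptively, not inferentially, at high traffic concentrations.
* Inland ports are out of scope by construction (excluded by the
  distance cutoff), as is any freshwater climatology that could cover
  them.
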
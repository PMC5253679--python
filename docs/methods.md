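# Methods

## Exposure from daily temperature extremes

The diurnal temperature course on each calendar day is modelled as
`T(t) = M + A·sin(2πt)` with `M = (Tmax+Tmin)/2`, `A = (Tmax−Tmin)/2`,
fitted within each day from that day's own extremes (no cross-midnight
blending). The fraction of the day above a threshold τ is then

- 1 if τ ≤ Tmin, 0 if τ ≥ Tmax,
- `1/2 − arcsin((τ−M)/A)/π` otherwise,

and a flat day (`A = 0`) contributes the indicator of `Tmin > τ`. Bin
times are differences of this fraction at consecutive edges, so per-day
times telescope to exactly one day across (−∞, ∞) and summing over days
commutes with the differencing (the per-season implementation exploits
this). Bins are half-open `[low, high)`: a temperature exactly at an edge
belongs to the upper bin. Fine bins are 1 °C from 0 to 39 °C; covariate
bins pool them to 3 K, with all time ≥ 39 °C in one top bin (treated as
centred at 40 °C when a midpoint is needed) and time below 0 °C excluded
from the covariates — its effect belongs to the regression intercept.
Seasons are fixed calendar windows; a window spanning the year boundary
(winter wheat, Oct 15 – Jul 15) is assigned to its harvest year, and leap
days are kept when they fall inside the window. Missing season days are
an error, never silently filled.

County records are crop-area-weighted means over member cells, with
weights renormalized within each county for the chosen water regime (so
aggregation is invariant to rescaling a county's weights by any positive
constant); regime-specific weight columns are honoured when present,
otherwise a common crop-area weight is used for both regimes. Counties
are classified rainfed when the rainfed crop-area share is ≥ 90%,
irrigated when the irrigated share is ≥ 75%, and excluded otherwise.

## Panel estimation

The within (fixed-effects) transformation demeans response and covariates
by county; slopes come from least squares on the demeaned system and are
algebraically identical to an explicit county-dummy regression (asserted
against statsmodels OLS in the tests). County effects are recovered from
group means; only the sum `α₀ + c_i` is identified, and the reported
split normalizes the county effects to mean zero. The design is validated
before fitting: columns constant within counties and any remaining linear
dependences are detected by pivoted QR and reported by name. This guard
matters in this design: if no county-year ever has time below 0 °C, the
pooled bins sum to the (constant) season length and the step design
becomes collinear after demeaning.

The piecewise-linear response form replaces the 14 bin columns with a
degree-day pair around a knot (default 30 °C), built from fine-bin times
at bin midpoints: `Σ_h t_h·clip(mid_h, 0, knot)` and
`Σ_h t_h·max(0, mid_h − knot)`.

Coefficient covariance is a spatial HAC sandwich: Ω sums
`x_i e_i e_j x_j'` over same-year observation pairs whose county
centroids lie within the cutoff (default 3°, Euclidean distance in
degrees, uniform kernel). Great-circle distance and a Bartlett taper are
available as configuration, and there is deliberately no serial
(within-county across-year) term; the cutoff is the only smoothing
choice. With the cutoff below the minimum inter-county distance the
estimator equals HC0. Confidence intervals use normal critical values —
residual degrees of freedom are in the hundreds to thousands in any panel
worth fitting. Two fits "significantly diverge" at a bin when their
closed confidence intervals are disjoint; a shared endpoint counts as
overlap (conservative counting). Ensemble medians across yield sources
use the numpy convention (even counts average the two middle values).

Comparisons between observed and simulated curves are always fitted on
the inner-join county-year subset of all panels involved (asserted by
equal sample sizes), so interval differences reflect responses, not
samples.

## Decomposition

A temperature range R with boundaries on pooled-bin edges gets the
multiplicative change factor `exp(Σ_{h∈R} γ_h·E_h)`, with `E_h` the mean
per-season exposure over the county-years of the chosen panel
(county-years weighted equally; the canonical ranges are <30, 30–36 and
>36 °C, and the total is their product by exponent additivity). The
future loss below 36 °C is `1 − (F_fut,<30·F_fut,30–36)/(F_hist,<30·
F_hist,30–36)`; the >36 °C factors cancel by construction (asserted).
Tabulated factors are rounded to two decimals and losses to integer
percent; full precision is kept internally. The packaged reference factor
table reproduces published losses of 49% (maize), 40% (soybean) and 22%
(wheat).

## Synthetic data: what it emulates and what it does not

The weather generator produces a seasonal sinusoid (coldest mid-January)
plus an AR(1) anomaly split evenly between a region-wide and a
cell-specific component, a lognormal diurnal range, a small latitudinal
mean gradient, and Bernoulli–gamma precipitation. Defaults (annual mean
11 °C, seasonal amplitude 14 °C, diurnal range 11 °C, anomaly sd 3.5 °C
with lag-1 autocorrelation 0.7, 35% wet days of mean 6.4 mm) emulate a
US corn-belt climate: maize seasons average roughly 7–11 days above
30 °C, every 3 K bin from 0 to >39 °C is occupied with year-to-year
variance, and early-season frost keeps below-0 time strictly positive
(which, as noted above, the step design needs). A uniform
`warming_offset` produces "future" scenarios whose exposure histograms
shift toward hotter bins. Not emulated: weather fronts and spatial
advection, precipitation–temperature dependence, realistic geography.

The statistical yield generator runs the regression equation itself with
known coefficients (an inverted-U over bins: mildly positive to 27 °C,
−0.006/−0.04/−0.06/−0.08 per day in the 30–33/33–36/36–39/39–42 bins),
county effects N(0, 0.2), small state trends, and Gaussian residuals with
exponential spatial covariance `σ² exp(−d/r)` over county centroids,
Cholesky-sampled independently per year (σ = 0.10, r = 0.5° by default —
the exponential form is an assumption made to exercise the spatial HAC
estimator, not a claim about real residuals). Trend covariates use the
same centered-year convention as the estimator, so noiseless panels
identify every slope exactly (to ~1e−15 in practice; the tests require
1e−8).

The mechanistic surrogate is a single-layer soil-water bucket: daily
evaporative demand `3.0 + 0.35·max(0, Tmean − 25)` mm (the 25 °C
reference places stress onset near the ~30 °C response inflection;
mid-season demand of 3–6 mm/day is standard agronomy), supply capped by
the bucket, bucket gaining rain and losing supply within [0, 120 mm],
irrigated runs refilled to capacity daily (hence zero stress, constant
yield). Log yield falls linearly with seasonal mean stress (sensitivity
2.0 from a potential of log 10 t/ha). Heat therefore damages yield *only*
through water stress, which is exactly what makes the generator useful:
a panel fit to rainfed surrogate yields shows significantly more negative
coefficients in the hottest occupied bins than a fit to irrigated
surrogate yields, the qualitative contrast the comparison module is built
to detect. The surrogate has no phenology, CO₂ physiology, nutrient
limitation or direct heat damage, so passing tests demonstrate the
pipeline's ability to detect a water-mediated temperature response, not
the realism of any particular crop.

## Problem sizes and numerical choices

The test suite runs its statistical checks on 200-county × 2-cell,
31-year panels (6 200 county-years, 36 slope parameters with 10 states) —
large enough that normal-theory intervals and the spatial HAC estimator
operate in their intended regime while a 200-replicate coverage study
completes in well under a minute. CI calibration is required per bin to
lie in [90%, 99%] at the 95% level over 200 replicates. The quadrature
oracle for the sinusoid primitives uses 4×10⁶ midpoint samples of one
diurnal cycle (empirical-CDF error ≲ 3×10⁻⁷, comfortably inside the
1e−6 tolerance). The Conley implementation is compared to an O(n²)
double-loop oracle at 1e−12 on small panels. Exposure conservation
(pooled bins + below-0 time = season length) is enforced at 1e−9 per
county-year. Degenerate inputs have defined behaviour throughout: flat
days, zero-weight counties (dropped with a warning), nonpositive yields
(dropped with a logged count), empty panels and rank-deficient designs
(errors naming the offending columns).

## Known limitations

- Distances default to Euclidean degrees, which distorts east–west
  distances at high latitude; great-circle distance is available but the
  3° cutoff convention then needs a km equivalent.
- No uncertainty is propagated onto change factors or the future-loss
  ratio (point estimates only).
- No bootstrap or wild-cluster inference; the spatial HAC kernel has no
  serial term, so within-county autocorrelation beyond the fixed effects
  is uncorrected.
- The synthetic region map has no real geography; county centroids are
  weighted cell means on a rectangular grid.
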
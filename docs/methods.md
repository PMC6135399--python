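# Methods

## Thermal time

Daily growing degree days are `max(0, T̄ − T_b)` with `T̄` the arithmetic
mean of the daily extremes when no measured mean is available (the
conventional De Candolle choice) and `T_b = 10 °C` for chia.  Clamping is
applied per day, before summation, so the cumulative series is
non-decreasing by construction and additive over concatenated date ranges.
Day 0 is the sowing date and ADD accumulates from sowing; whether published
stage tables count from sowing or emergence is ambiguous in this
literature, so the package simply reports the ADD of whatever stage DAS it
is given.  No upper temperature cutoff is applied by default — chia's
maximum growth temperature (36 °C) would suggest one, but the accumulation
rule used in the trials has none; an optional `tceiling` exists.
Fractional harvest days are placed on the thermal axis by linear
interpolation between daily cumulative values.

## Reference evapotranspiration and irrigation dosing

ETo follows the FAO-56 Penman–Monteith combination equation exactly as
printed, with the standard auxiliaries: Tetens saturation vapour pressure,
its slope Δ (the conventional 4098 constant, which rounds 17.27 × 237.3 and
therefore agrees with the true derivative to ~4 × 10⁻⁵ relative),
γ = 0.000665 P, and P defaulting to 101.3 kPa (a barometric elevation
correction is available but off, as the sites sit at 135 m and 420 m where
the effect on ETo is ~1 %).  Missing `e_a` is derived as rh/100 · e_s(T̄);
`e_s` is the mean of the saturation pressures at the daily extremes.
Computed ETo may be negative on low-energy days and is preserved as such;
the scheduler, however, lets negative days contribute zero to its
accumulator (a plot cannot be "un-irrigated").

The scheduler walks the daily series, accumulating ETo and emitting an
irrigation event whenever the running sum first reaches the trigger depth;
the applied depth is `fraction × accumulated` and the accumulator resets.
The default trigger is 8 mm because the trials' worked dosing example uses
8 mm within the stated 5–10 mm criterion band.  Residual sub-trigger demand
at season end emits no event (whether the real trial irrigated it is
unknown).  Total applied depth is then exactly linear in the dose fraction,
which is the designed contrast between the 100 % and 40 % treatments.

## Double-logistic model and fitting

The model is implemented with the published sign convention — `−m_S` in the
growth exponent, `+m_A` in the senescence exponent, and no constant offset
— so fitted coefficient tables are directly comparable with published ones:
`y_min` may be strongly negative and `m_S` negative, as in the published
rows.  Both logistic terms are evaluated through the numerically saturating
sigmoid, safe for arbitrarily large exponents.

Two structural facts shape the fitter:

* **Mirror symmetry.**  The curve is exactly invariant under
  `(m_S, S) ↔ (−m_A, A)`.  Fits can therefore converge in either branch;
  the result is folded back to the convention `S ≤ A` (growth inflection
  before senescence inflection), which is how the published tables order
  the parameters.  The Jacobian columns are permuted and sign-flipped
  accordingly before the covariance is formed.
* **Weak identifiability of steep rates.**  When a rate parameter is large
  enough that the whole sigmoid transition falls between observation
  points, the likelihood is flat in that parameter.  Several published
  leaf-area rows (m_A up to 0.93 (°C·d)⁻¹ against a 25-ADD cadence) sit in
  this regime, so exact rate recovery is only expected for rates the
  sampling can resolve.

Minimisation is `scipy.optimize.least_squares(method="lm")` from a
heuristic start — asymptotes pad the observed range by 10 %, inflections at
the half-range crossings, rate magnitudes 4/width with signs taken from the
local data direction — plus seeded random restarts (default 5) and one
declining-series alternative start; the lowest SSE wins.  Box bounds switch
the solver to the reflective trust-region variant.  Convergence tolerances:
relative cost reduction 10⁻¹⁰, step norm 10⁻¹², at most 5000 evaluations
per start.

Goodness of fit reports two residual scales because the published tables
print two: "RMSE" uses the n denominator and "Error" the n − 6 denominator
(their ratio pattern √(n/(n−6)) in the published rows supports this
reading); R² = 1 − SSE/SST, and p comes from the regression F test on
(5, n − 6) degrees of freedom.  Table averaging ("Average SD"/"Average IT"
rows) is the element-wise arithmetic mean of coefficients and fit
statistics alike.  Comparing two fitted coefficient sets uses a paired
two-sided t test across the six values; the published description of this
comparison is terse and a fit-comparison F test would be an equally valid
reading — the paired t was chosen as the most literal one, with the
degenerate all-equal case defined as p = 1.

## Growth indices

Rates are per calendar day (the units in which these indices are defined)
while the reporting axis is thermal time; functional derivatives taken with
respect to ADD are converted with the season's mean ADD-per-day.  Interval
indices follow Hunt's formulas on treatment-mean trajectories (the mean of
the harvested plants per date), with the equal-area limit of NAR handled
explicitly.  "LWR" here denotes leaf area per total dry mass — the trials'
usage, conventionally called LAR — and both names are exposed, related by
the per-kg factor of 1000.  SLW on functional grids requires a leaf mass
fraction model (scalar or callable); the identity RGR = NAR × LAR holds to
machine precision on any grid, and negative RGR/CGR during senescence is
preserved.  Plant densities default to 50 m⁻² (sowing-date trial) and
60 m⁻² (irrigation trial, the midpoint of the thinned 55–65 band).

## Synthetic trials

The generator is statistical, not mechanistic: no radiation interception,
water balance or stress physiology.  Weather is a sinusoidal annual
climatology (southern-hemisphere peak in mid January) with seeded Gaussian
daily anomalies shared by the extremes; humidity, wind and net radiation
are clipped Gaussians around site means.  The site parameters were set so
the *thermal timelines* match the trials' stage records — a December sowing
at the warm-temperate site reaches ~1100–1200 ADD by 121 DAS; the desert
site reaches ~490–500 ADD by 70 DAS and ~700 ADD over the 151-day season —
rather than to the sites' extreme-month normals, which the desert site's
record could not satisfy simultaneously.

Plant observations are Gaussian draws around double-logistic truth curves,
truncated above a small positive floor by redrawing (not clamping, to avoid
a point mass).  The default truth sets are the published coefficient rows
for the four treatments, and the default noise sds are the published fit
RMSEs (biomass 0.24–1.29 g, leaf area 36–137 cm²), so a fit of generated
data should reproduce the published goodness of fit.  Organ masses follow a
phenology-indexed allocation (leaf fraction 0.45 before flowering declining
to 0.12, inflorescence rising to 0.35, remainder split 3:1 stem:root) and
sum exactly to the drawn total; within- and between-plot variance is pooled
into a single sd since no partition is reported.  A deficit-effect helper
scales the (y_max − y_min) range of truth curves by the observed reductions
(54 % biomass, 43 % leaf area) while preserving the shape parameters.

**Known limitation.**  The published coefficient rows inserted into the
published curve form do *not* reproduce the rise-and-fall trajectories of
the trials' figures (the SD1 biomass row evaluates to ~199 g at t = 0 and
declines monotonically over the observed window).  The package follows the
printed convention without reparameterisation, so the synthetic trials are
self-consistent — generation, fitting, recovery and all statistics operate
on the same curve family — but their trajectories, and hence the *signs and
locations* of index extremes, are those of the printed coefficient sets,
not of the figures.  Passing tests therefore demonstrate correctness of the
machinery and recoverability of parameters under realistic noise, not
agreement with the unpublished raw field trajectories.

## Statistics

The irrigation trial's declared split-plot design is simplified to
per-harvest one-way comparisons of treatment plot means, which is how
per-date significance is reported on growth curves; no correction for
multiple testing across dates is applied (none was in the source
protocol).  Duncan critical values are computed from the studentized range
distribution at protection level 1 − (1−α)^(p−1) with the harmonic mean
group size, rather than interpolated from printed tables, for
reproducibility at arbitrary error degrees of freedom; for two groups this
reduces exactly to Fisher's LSD, which the tests verify.  Letter assignment
extends non-significance over whole spans (largest spans first), making the
letters order-consistent by construction.  Zero-variance inputs to the
correlation matrix yield flagged NaNs, never a silent zero.

## Problem sizes and determinism

The recovery study fits 57-point series (0–1400 ADD at 25-ADD cadence),
20 replicates, ~12 optimiser starts each; a full synthetic trial is 1080 or
1400 plant records.  Every stochastic step takes an explicit seed; the
pipeline derives per-stage substreams from one root seed and records it in
a manifest, and rerunning with the manifest seed reproduces every output
byte for byte.
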
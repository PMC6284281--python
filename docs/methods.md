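# Methods

## Model and assumptions

Maize phenology is modelled as temperature-driven rate accumulation.
A developmental phase carries a dimensionless state D that integrates the
daily development rate, D = Σ r(T(t)) Δt with a fixed one-day step, and
the phase completes when D reaches 1. Two phases are tracked — vegetative
(emergence to tasseling/silking) and reproductive (flowering to
physiological maturity) — chained so the reproductive phase starts on the
day after the interpolated flowering time. A sowing-to-emergence offset
(default 7 days, admissible 0–30) is added to form the length of the
growing period. The model assumes adequate water and nutrients (no stress
modifiers) and no photoperiod effect, which is defensible for tropical
maize near the equator; neither assumption is safe for temperate
germplasm or strongly photoperiodic crops.

The rate curve r(T) is pluggable. Built-ins: Briere-1
a·T·(T−Tb)·√(Tm−T) and Briere-2 a·T·(T−Tb)·(Tm−T)^(1/µ) (the canonical
form; µ = 2 reduces exactly to Briere-1), linear degree-day (T−Tb)/TT,
quadratic a·(T−Tb)·(Tm−T), Gaussian, Logan-6, Lactin-2, and a
cardinal-temperature beta. Bounded-support curves are clamped to zero
outside (Tb, Tm): a square root of a negative number is not a rate, and
development ceasing beyond the thermal thresholds is the biological
premise of the whole family. Temperatures are °C throughout.

## Completion rule and within-day temperature

Accumulation defines no completion rule by itself, so the engine declares
the phase complete at the first day j with cumulative D ≥ 1 and
interpolates linearly within that day, duration = j + (1 − D_{j−1})/r_j.
This removes the ±1-day quantisation a hard daily threshold would impose
and makes constant-temperature durations equal 1/r(T) to machine
precision. The daily driving temperature defaults to (Tmin+Tmax)/2; a
sine mode instead averages the rate over an idealised diurnal sine between
the extremes, exposing the Jensen gap of the nonlinear curve for
sensitivity checks. Observed phase durations are whole days (field scoring
records dates), so the reproductive phase starts at the flowering day
rounded up.

## Fitting

Each trial contributes one point: observed rate 1/duration against the
site's representative phase-mean temperature. Fitting rate-vs-temperature
points (rather than matching accumulated durations through a full daily
series) is the default because observed rates are what the curve is
defined on and reported fit errors in this literature are rate-scale; a
duration-space objective via full accumulation remains available through
the engine for comparison. The weighted least-squares problem is solved
with `scipy.optimize.least_squares` using the trust-region-reflective
method — damped Gauss–Newton steps of the Levenberg–Marquardt type,
chosen over classical unconstrained LM because the cardinal temperatures
are kept inside biologically interpretable bounds (Tb ∈ [0, 20] °C,
Tm ∈ [25, 50] °C, a > 0, µ ∈ (0.1, 10]). Tolerances: ftol 1e-12,
xtol 1e-10, at most 500·p residual evaluations.

Initial values come from a deterministic multi-start: a Tb × Tm lattice
{5, 8, 11} × {35, 40, 45} °C with the rate constant scaled so the curve
peak matches the maximum observed rate (analogous data-driven grids for
the non-Briere forms); the start with the lowest RSS wins, so repeated
runs are byte-identical. Standard errors use the Gauss–Newton
approximation sqrt(diag(RSS/(n−p)·(JᵀJ)⁻¹)); a rank-deficient Jacobian
yields "undefined" with a warning rather than fabricated numbers.
Parameter estimates landing on a bound are flagged.

## Selection

Goodness of fit: R² = 1 − RSS/TSS (TSS about the observed mean), adjusted
R² = 1 − (1−R²)(n−1)/(n−k−1), RMSE in rate units. Model comparison uses
the least-squares criteria AIC = n·ln(WRSS) + 2p (lower better) and
MSC = ln(WTSS/WRSS) − 2p/n (higher better); on common data they satisfy
MSC = ln(WTSS) − AIC/n exactly, so their rankings always coincide — both
are reported because both are conventional. Weights default to 1.
Ranking is AIC-ascending with one adjustment: a nested extension
(Briere-2 over Briere-1) must justify its extra parameter by the
extra-sum-of-squares F test at α = 0.05, otherwise it is demoted below
its parent. This guards against the extra exponent winning on noise
alone; raw-AIC ordering is available via `nested_f_alpha=None`. Absolute
AIC values depend on an arbitrary additive constant (e.g. WRSS vs WRSS/n
inside the log) and are only meaningful within one data set.

## Independent-site evaluation

The packaged `table3.csv` carries observed and predicted durations for 22
varieties at three evaluation sites withheld from calibration; agreement
per site is the Pearson correlation of observed vs predicted days, its
adjusted R² with k = 1 (the model prediction is the single predictor),
RMSE in days and mean bias. The per-site, k = 1 convention is adopted
because it reproduces the reference adjusted-R² values exactly from the
correlations. `table2.csv` transcribes published Briere parameter
estimates for eight varieties; it is summarised (Tb and RMSE extremes)
but never chained into duration predictions — its printed rate constants
are on an inconsistent scale (rates of ~0.5/day would imply 2-day
phases), evidently a typesetting loss of a scale factor.

## Spatial mapping

ESRI ASCII grids (6-line header, rows north to south, cell-centre values,
lower-left georeferencing) are read and written with a strict parser:
ragged rows, malformed headers and row-count mismatches are errors with
line numbers. A climatology stack is 12 monthly Tmin + 12 Tmax rasters,
co-registered or rejected. Monthly normals become daily series either by
holding each month constant (step) or linearly interpolating between
month midpoints with year wrap-around (smooth, default; knots are
preserved exactly). Two mapping modes: `inverse_rate` evaluates 1/r at
the cell's annual mean temperature — the direct rate-inversion reading —
and `accumulation` (default) runs the daily engine from a sowing
day-of-year on a two-year tiled series, which respects seasonality. The
modes agree exactly on temporally constant climates. Nodata is absorbing:
missing temperature in any layer, or a cell outside the variety's thermal
window (the phase can never complete), maps to the nodata sentinel, the
two causes counted separately in logs. The suitability mask keeps cells
with any nonzero non-nodata value (tolerating 0/1 and 0/255 dialects).
The sowing day for maps is a required input, not a default — it is
agronomic policy, not a property of the model.

## Synthetic data

The generator emulates a 16-trial multi-environment set on an altitudinal
transect: 16 phase-mean temperatures evenly spanning 12–36 °C, wide
enough to identify both cardinal temperatures of a truth with Tb = 9 and
Tm = 40 °C. Observed durations are round(1/(r_true(T) + ε)) with ε
Gaussian on the rate scale (default SD 5·10⁻⁴, roughly the reported
rate-RMSE magnitude of real fits), redrawn while non-positive; rounding
to whole days mimics field scoring and can be disabled
(`round_durations=False`) for exact-recovery oracles where the only
perturbation must be the configured noise. Weather is a 365-day sinusoid
with configurable mean, amplitude and daily noise; rasters carry a linear
north-south gradient, a small seasonal cycle, seeded nodata holes and a
seeded suitability mask. All generators are bit-reproducible from an
integer seed.

What passing tests on these data do show: the estimation machinery
recovers known truths, the selection criteria prefer the generating curve,
and every pipeline stage composes correctly. What they do not show:
performance under real trial data's correlated errors, site-specific
microclimate deviations from station temperature, genotype × environment
interaction, or stress effects — none of which the generator simulates.

Under the default conditions the generating Briere-1 curve wins the
ranking in 20/20 noise-free replicates and about 75% of replicates at
rate-noise SD 5·10⁻⁴ (the flexible 4-parameter beta and Lactin curves win
the rest on small AIC margins — with 16 points and noise comparable to
the signal at cool sites, that ambiguity is statistically real, and the
whole-day rounding adds noise of the same order as ε itself).

## Problem sizes

Default experiment sizes — 16-site trials, 50-replicate recovery studies,
20-replicate selection studies, 3×3 to 8×8 rasters, ≤ 2-year daily series
— are chosen so any single study runs in seconds on one core while the
Monte-Carlo medians are stable; all sizes are arguments, not constants.

## Known limitations

- Single parameter set per variety by default (vegetative and reproductive
  phases share a curve); separate parameter sets are supported but not
  auto-fitted per phase.
- No uncertainty propagation from parameter SEs into predicted durations
  or maps (no bootstrap/Bayesian machinery).
- The inverse-rate mapping mode ignores seasonality entirely; the
  accumulation mode assumes the monthly climatology repeats identically
  year over year.
- No reprojection or resampling: all rasters must be co-registered ESRI
  ASCII grids.
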
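# maizephen

Temperature-driven phenology modelling for tropical maize: fit
development-rate curves to multi-environment trial data, pick the best
model statistically, predict phase durations by thermal-time accumulation,
validate at independent sites, and map the length of the growing period
over gridded climatologies.

## The problem

In the tropics the timing of maize development — emergence, flowering
(tasseling/silking), physiological maturity — is controlled almost
entirely by temperature: photoperiod sensitivity is negligible near the
equator and bred against in tropical germplasm. Breeders already record
phenology dates in routine multi-environment yield trials, so those trials
can be recycled to calibrate a predictive phenology model per variety and
then project it across agro-ecologies. That is what this package does, for
anyone who needs location-specific maturity predictions: breeders planning
flowering synchrony, agronomists advising on variety choice, or modellers
assessing climate-change impacts.

## The model

Development through a phase is a dimensionless state accumulated daily,

    D = Σₜ r(T(t)) Δt,   Δt = 1 day,

with the phase (vegetative: emergence→flowering; reproductive:
flowering→maturity) complete when D ≥ 1. The development rate r (= 1/phase
duration at constant temperature) follows a nonlinear thermal response.
The central curve is the Briere model,

    Briere-1:  r(T) = a · T · (T − T_b) · √(T_m − T)
    Briere-2:  r(T) = a · T · (T − T_b) · (T_m − T)^(1/µ)

zero outside the thermal window (T_b, T_m), where T_b is the base
temperature, T_m the ceiling, a an empirical rate constant, and µ a shape
exponent (µ = 2 recovers Briere-1). An extensible registry ships eight
classical alternatives (linear degree-day, quadratic, Gaussian, Logan-6,
Lactin-2, cardinal-temperature beta). Curves are fitted to (site mean
temperature, 1/observed duration) points by bounded damped least squares
with a deterministic multi-start, and compared by R², adjusted R²,
AIC = n·ln(RSS) + 2p and MSC = ln(TSS/RSS) − 2p/n, with the nested
Briere-1 ⊂ Briere-2 pair arbitrated by an extra-sum-of-squares F test
before selection.

## Worked example

Fit the whole catalogue to 16 synthetic trials generated from a known
Briere-1 truth (a = 2·10⁻⁵, T_b = 9 °C, T_m = 40 °C) with realistic rate
noise (`python examples/02_fit_and_select.py`):

```
    model  n_params       r2   r2_adj     aic     msc        rmse  plausible
  briere1         3  0.99876  0.99844 -195.65  6.3136  0.00045843       True
  briere2         4  0.99876   0.9983 -193.65  6.1887  0.00045842       True
     beta         4  0.99863  0.99814 -192.17  6.0962   0.0004801       True
 ...
best model: briere1
  a = 1.9996e-05 (SE 4.3e-07)
  tb = 8.902 (SE 0.24)
  tm = 39.912 (SE 0.18)
```

The generating model wins the ranking and its cardinal temperatures are
recovered to a fraction of a degree. Validating the packaged reference
predictions at the three independent evaluation sites
(`python examples/04_evaluate_sites.py`):

```
Kiboswa   r = 0.892  adj R² = 0.786  RMSE = 2.29 d  bias = -1.14 d  (n = 22)
Nyahera   r = 0.712  adj R² = 0.482  RMSE = 1.81 d  bias = -1.00 d  (n = 22)
Vihiga    r = 0.920  adj R² = 0.838  RMSE = 1.22 d  bias = -0.59 d  (n = 22)
```

Correlations near 0.9 with biases ~1 day mean the fitted curves transfer
to sites not used in calibration. The other examples show the rate curves
(`01`), a sowing-to-maturity calendar from daily weather (`03`), and
duration mapping over a gridded climatology with a suitability mask (`05`).

A thin CLI mirrors the workflow: `maizephen simulate | fit | select |
predict | evaluate | map` (see `maizephen --help`).

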
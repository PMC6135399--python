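# chiagrow

Growth analysis of chia (*Salvia hispanica* L.) field trials: thermal time,
FAO-56 reference evapotranspiration and deficit-irrigation dosing,
double-logistic growth-curve fitting, and classical functional growth
analysis.

## What this is for

Chia is a short-day crop being adapted to new latitudes, where the questions
that matter are agronomic: when to sow, and how much of the evaporative
demand to replace with irrigation.  This package reimplements the analysis
pipeline of two such trials — a **sowing-date trial** (SD1 sown 7 Dec, SD2
sown 31 Dec; 5 replicates; 50 plants m⁻²) and a **deficit-irrigation trial**
(IT1 = 100 % ETo, IT2 = 40 % ETo; 6 blocks; ~60 plants m⁻²) — as a reusable
library plus a set of numbered analysis drivers.  Because the raw field data
are not redistributable, a first-class synthetic-data module regenerates
both trials' statistical structure (replication, harvest cadence, noise at
the published residual magnitudes), so the whole pipeline runs and is tested
end to end without any download.

## The models

**Thermal time.** Development is clocked in accumulated growing degree days
(ADD) from sowing, `ADD_k = Σ max(0, T̄_i − T_b)` with base temperature
`T_b = 10 °C`.

**Reference evapotranspiration.** Daily water demand is the FAO-56
Penman–Monteith ETo (mm d⁻¹):

    ETo = [0.408 Δ (Rn − G) + γ · 900/(T+273) · u₂ (e_s − e_a)]
          / [Δ + γ (1 + 0.34 u₂)]

Because no crop coefficient is known for chia, irrigation is triggered on
ETo itself: each time the accumulated demand reaches a trigger depth
(default 8 mm, within the 5–10 mm criterion band), the plot receives
`fraction × accumulated` litres per m² (1 mm ≡ 1 L m⁻²).

**Growth curves.** Whole-cycle dry biomass and leaf area are described on
the thermal axis by a six-parameter double logistic:

    y(t) = y_min + (y_max − y_min) · [ 1/(1 + e^{−m_S (t − S)})
                                     + 1/(1 + e^{ m_A (t − A)}) ]

with growth inflection `S`, senescence inflection `A` and rates `m_S`,
`m_A`.  Fitting is damped least squares (Levenberg–Marquardt) from a
data-driven start with seeded random restarts; the goodness-of-fit columns
are RMSE = √(SSE/n), residual standard error √(SSE/(n−6)), R², and the
regression-F p value.

**Growth indices.**  From Hunt's interval formulas and from the fitted
curves: RGR (g g⁻¹ d⁻¹), NAR (g cm⁻² d⁻¹), LAR/LWR (cm² g⁻¹, cm² kg⁻¹),
SLW (g cm⁻²), CGR (g m⁻² d⁻¹) and LAI, with the identity RGR = NAR × LAR
holding exactly on functional grids.

**Statistics.** One-way ANOVA per harvest, Duncan's multiple range test at
α = 0.05 (critical points from the studentized range at protection level
1 − (1−α)^(p−1)), and Pearson correlation matrices among indices.

## Worked example

```python
import numpy as np
from chiagrow import (BIOMASS_COEFFICIENTS, DoubleLogisticCoefficients,
                      double_logistic, fit_double_logistic)

truth = DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc["SD1"])
t = np.arange(0, 1401, 25.0)                      # thermal-time grid, ADD
rng = np.random.default_rng(1)
y = double_logistic(t, truth) + rng.normal(0, 0.4906, t.size)
fit = fit_double_logistic(t, y, restarts=10, seed=1)
print(f"S = {fit.coefficients.s:.1f} ADD, R^2 = {fit.r2:.4f}")
```

prints

```
S = 1093.4 ADD, R^2 = 0.9999
```

i.e. from one season of noisy synthetic biomass (Gaussian sd 0.4906 g, the
published SD1 residual magnitude) the fitter recovers the growth inflection
within 0.7 % of the generating value S = 1086.756 ADD, at the published
determination level (> 0.98); the median over 20 such replicates lands
within 0.4 %.

The full analysis — simulate both trials, accumulate thermal time, compute
ETo and the irrigation schedules, fit all curves, derive indices, run the
statistics — is the numbered scripts:

```sh
python analysis/01_simulate_trials.py
python analysis/02_thermal_time.py
python analysis/03_eto_irrigation.py
python analysis/04_fit_growth_curves.py
python analysis/05_growth_indices.py
python analysis/06_statistics.py
```

Each prints what it found and writes its tables under `results/analysis/`.
The same stages are available as one call, `chiagrow.run_pipeline`.

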
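# pmidelim

Delimitation of the postmortem interval (PMI) from skeletal-muscle protein
degradation.

## The problem

Estimating time since death beyond the first day is one of the hardest
routine questions in forensic medicine. Degradation of abundant muscle
proteins offers a biochemical clock: as a body decomposes, well-defined
split products of cardiac troponin T (cTnT), desmin, and the autolyzed
(activated) form of calpain 1 appear on Western blots and casein zymograms
in a predictable order, while tropomyosin stays intact and serves as a
negative control. Because decomposition is driven jointly by time and
temperature, the natural axis is the **accumulated degree-day (ADD)**,

```
ADD(t) = Σᵢ max(Tᵢ, 0) · Δtᵢ / 24   [°d]
```

the time integral of ambient temperature (°C, floored at 0 °C) over the
piecewise-constant temperature history of the body, in day units.

`pmidelim` implements the full pipeline for practitioners who have (a) a
case's temperature history, (b) densitometric traces of its gel lanes, and
(c) a calibrated marker panel:

1. **`pmidelim.thermal`** — forward ADD computation and its monotone
   inversion back to clock-time bounds (interval-valued across 0 °C
   plateaus, where accumulation stalls).
2. **`pmidelim.densitometry`** — binary band calls from 1-D lane traces:
   ladder calibration (log-linear in molecular weight), rolling-minimum
   baseline, band-window integration, and the background rule that any
   signal below 1 % of the lane's dominant band is not a band.
3. **`pmidelim.calibration`** — per marker and demographic subgroup:
   Spearman screening of presence against ADD (exact permutation p-values
   at small n), then, for markers passing the p ≤ 0.01 gate, a logistic
   regression `P(present | ADD) = expit(β₀ + β₁·ADD)` fitted by damped
   Newton/IRLS with separation detection and an optional Firth penalty.
   The calibrated outputs are the ADD thresholds
   `P50 = −β₀/β₁` (the product becomes more likely present than absent) and
   `P95 = (ln 19 − β₀)/β₁` (the product is expected in ≥ 95 % of cases).
4. **`pmidelim.delimitation`** — a case's binary marker vector is combined
   through an independent-Bernoulli likelihood over a dense ADD grid; the
   highest-density region at the requested level gives ADD bounds, which the
   temperature history converts to PMI bounds in hours postmortem.
5. **`pmidelim.cohort`** — a seeded synthetic-cohort and lane-trace
   generator with the structure of the 40-case calibration study (PMI
   4–92.8 h, 4 °C mortuary cooling in 28/40 cases, marker presence drawn
   from logistic curves of true ADD with the desmin nesting constraints),
   so every stage is testable against known ground truth.

The model/results layout follows statsmodels: `MarkerLogit(...).fit()`
returns a `MarkerLogitResults` with estimates, standard errors, diagnostics
and `summary()`; `PanelCalibration` builds the product × subgroup
calibration table; `PanelDelimiter` consumes calibrations and produces
`PmiInterval` objects.

## Worked example

```python
from pmidelim import (GeneratorConfig, PanelCalibration, PanelDelimiter,
                      TemperatureProfile, cohort_frame, default_panel,
                      generate_cohort)

cases = generate_cohort(GeneratorConfig(n_cases=200, seed=42))
results = PanelCalibration.from_cohort(cohort_frame(cases),
                                       default_panel()).fit()
print(results.summary())
```

```
Marker calibration table (presence vs ADD)

product       group                n  abs pres     rho       p    P50    P95  status
------------------------------------------------------------------------------------
ctnt_dp1      Total              200   18  182   0.442   0.000    2.5    6.0  ok
ctnt_dp2      Total              200   82  118   0.459   0.000    9.0   29.9  ok
desmin_dp1    Total              200   80  120   0.342   0.000    7.7   37.3  ok
desmin_dp2    Total              200  119   81   0.549   0.000   15.4   32.5  ok
desmin_dp3    Total              200  162   38   0.437   0.000   24.3   42.1  ok
calpain1_dp   Total              200  105   95   0.472   0.000   13.2   34.5  ok
```

Each row screens one degradation product's presence against ADD (Spearman's
ρ with its p-value) and, where the correlation passes the p ≤ 0.01 gate,
reports the calibrated thresholds: cTnT dp2, for example, becomes more
likely present than absent from ~9 °d onward and is expected in ≥ 95 % of
cases from ~30 °d. A case observed with the early markers present and the
late ones absent can then be delimited:

```python
delim = PanelDelimiter(results.curves("total"))
profile = TemperatureProfile.from_pairs([(24, 18.0), (72, 4.0)])
interval = delim.delimit(
    {"ctnt_dp1": 1, "ctnt_dp2": 1, "desmin_dp1": 1,
     "desmin_dp2": 0, "desmin_dp3": 0, "calpain1_dp": 0},
    profile=profile, level=0.95)
print(interval)
```

```
ADD in [1.9, 38.1] °d (hdr-0.95 (independent-marker likelihood, uniform ADD prior)); PMI in [2.5, 96.0] hpm [extrapolated beyond calibrated range]
```

The 95 % ADD region is mapped through the case's temperature history (24 h
at 18 °C at the scene, then 72 h of 4 °C cooling) into PMI bounds; because
the profile only accumulates 30 °d in total, the upper bound is truncated
at the profile's end and the interval is flagged as extrapolated beyond the
calibrated observation window.

The same pipeline is scriptable from a shell: `pmidelim simulate`,
`pmidelim bands`, `pmidelim calibrate`, `pmidelim delimit`,
`pmidelim add` (see `pmidelim --help`).

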
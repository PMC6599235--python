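# exmort

Estimation of the **excess mortality** of a chronic disease — the difference
Δm = m₁ − m₀ between the mortality rate of the diseased and the disease-free,
or equivalently the mortality rate ratio R = m₁/m₀ = 1 + Δm/m₀ — from
**aggregated** age-specific prevalence and incidence data.  No individual-level
follow-up is needed, which makes the approach usable with disease registers,
health-insurance claims tables, and published cross-sectional surveys, i.e.
wherever deaths cannot be attributed to the diseased or disease-free group
directly.

The package is aimed at epidemiologists and biostatisticians working with
chronic-disease surveillance data (dementia, diabetes, and similar
no-remission conditions).

## The model

In the illness-death model (states *Healthy* → *Ill* → *Dead*, no remission)
the age-specific prevalence p(t, a) obeys the transport PDE

```
(∂t + ∂a) p = (1 − p) { i − p (m₁ − m₀) }
```

with incidence rate i(t, a).  Three consequences drive everything here:

1. **Forward problem.** Along a characteristic t − a = const the PDE is a
   scalar ODE; the equivalent prevalence-odds θ = p/(1 − p) even has the
   explicit solution
   `θ(t,a) = ∫₀ᵃ i(t−s, a−s) exp(−φ(s)) ds` with
   `φ(s) = ∫₀ˢ [m₁−m₀−i](t−x, a−x) dx`,
   so prevalence can be computed from rates to any prescribed accuracy
   (`exmort.odds_at`, `exmort.cross_section`).
2. **Direct inversion.** Rearranging the PDE,
   `Δm = [ i − (∂t+∂a)p / (1−p) ] / p`: two prevalence cross-sections taken
   ΔT years apart give the directional derivative as a finite difference and
   hence Δm — this is `ExcessMortalityModel`.  Accuracy decays as the surveys
   move apart; with exact inputs the relative error of R stays below ~5 % for
   ΔT ≤ 3 years.
3. **Bayesian estimation.** When m₀ is unknown but the *general* mortality
   m = p·m₁ + (1−p)·m₀ is, the PDE can be written in terms of (m, R).  With
   log R(a) affine between ages 50 and 90, `MortalityRatioModel` evaluates the
   posterior of (R(50), R(90)) on a dense lattice — Gaussian likelihood with
   covariance diag(pⱼ(1−pⱼ)/nⱼ), uniform U(2, 9) × U(1, 2) or bivariate-normal
   priors — and reports the MAP and 95 % credible intervals.

A scenario generator (`dementia_scenario`, `diabetes_like_scenario`)
produces fully synthetic worlds with known rates for validation: Gompertz–
Makeham background mortality `m₀(t,a) = exp(−10.7 + 0.1a + t·ln 0.99)` and a
log-linear rate ratio (3 at age 60 falling to 1.5 at age 95 in the dementia
world).

## Worked example

Estimate the mortality rate ratio of dementia from two simulated surveys one
year apart:

```python
import numpy as np
import exmort as em

scenario = em.dementia_scenario()
ages = np.arange(65.0, 96.0, 5.0)
cs1 = em.cross_section(scenario, 1999.5, ages - 0.5, method="odds")
cs2 = em.cross_section(scenario, 2000.5, ages + 0.5, method="odds")

model = em.ExcessMortalityModel(
    cs1, cs2,
    incidence=lambda a: scenario.incidence_at(2000.0, a),
    m0=lambda a: scenario.m0_at(2000.0, a),
)
print(model.fit(ages=ages).summary())
```

```
Direct excess-mortality estimate
  midpoint calendar time: 2000
  ages: 65..95 (7 points)

 age   delta_m  midpoint_prevalence  derivative   ratio
  65 0.0255699            0.0113982  0.00162032 2.70516
  70 0.0359253            0.0229094  0.00318897 2.45308
  75 0.0498794            0.0451581  0.00611026 2.22367
  80  0.068228            0.0868229    0.011316 2.01521
  85 0.0915256             0.161855   0.0200822 1.82602
  90  0.119563             0.290398   0.0336097 1.65448
  95  0.150383             0.493814   0.0503721 1.49929
```

`delta_m` is the excess mortality per person-year at the midpoint year 2000,
`midpoint_prevalence` and `derivative` the two prevalence-based ingredients
of the inversion formula, and `ratio` the resulting R(a).  The true curve
falls from R(65) = 2.717 to R(95) = 1.500; with surveys only one year apart
the estimates are accurate to a few tenths of a percent.

The same pipelines are scriptable from the shell:

```sh
exmort simulate --delta-t 1 --ages 60:95:0.5 --out sim/
exmort direct sim/prevalence_t1.csv sim/prevalence_t2.csv \
       --incidence sim/incidence.csv --m0 sim/m0.csv --out results/
exmort bayes --initial initial.csv --target target.csv \
       --incidence incidence.csv --mortality mortality.csv --out fit/
```

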
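# Methods

## Model

`exmort` works in the illness-death (three-state) model of chronic-disease
epidemiology: *Healthy* and *Ill* individuals die at age- and time-specific
rates m₀(t, a) and m₁(t, a), healthy individuals contract the disease at the
incidence rate i(t, a), and — the defining property of a chronic condition —
there is no Ill → Healthy transition.  All rates are per person-year; ages
and times are decimal years.  Under these assumptions the prevalence
p(t, a) satisfies

    (∂t + ∂a) p = (1 − p) { i − p (m₁ − m₀) },                    (†)

a transport equation whose characteristics t − a = const are birth cohorts
on the Lexis diagram.  The model ignores migration: results apply to closed
populations, or ones where migrants carry roughly the resident prevalence.

Three reformulations of (†) are used:

* **Odds form.**  θ = p/(1 − p) satisfies a *linear* PDE with the explicit
  solution θ(t, a) = ∫₀ᵃ i(t−s, a−s) e^(−φ(s)) ds,
  φ(s) = ∫₀ˢ [m₁ − m₀ − i](t−x, a−x) dx.  Both integrals run along the same
  characteristic.
* **Inversion form.**  Δm = [ i − (∂t+∂a)p/(1−p) ] / p expresses the excess
  mortality in prevalence-based quantities only; with known m₀,
  R = 1 + Δm/m₀.
* **(m, R) form.**  Substituting m = p m₁ + (1−p) m₀ and R = m₁/m₀ gives
  (∂t + ∂a) p = (1 − p){ i − m·p(R−1)/(1 + p(R−1)) }, the right form when
  general mortality (a routinely published quantity) is known but m₀ is not.
  The denominator 1 + p(R−1) is bounded away from zero for R > 0, p ∈ [0, 1].

## Numerical solvers

**Odds integral** (`odds_at`): nested adaptive Gauss–Kronrod quadrature
(outer integral over the characteristic age s, inner integral for φ), with
an absolute tolerance on θ (default 1e-8; the inner tolerance is 100× tighter,
capped at 1e-10).  The routine raises if the quadrature error estimate
exceeds the requested tolerance, and rejects negative rates wherever it
evaluates them.

**Characteristic RK4** (`solve_along_characteristic`): classical fixed-step
fourth-order Runge–Kutta along t = t₀ + s, a = a₀ + s, default step 0.05
years with a final partial step.  Whole cross-sections launch each cohort at
age 0 with p = 0 — the chronic-disease initial condition of no prevalent
cases at birth, which the problem statement leaves implicit but which is the
only self-consistent choice for diseases acquired after birth.  Tiny
numerical overshoots of [0, 1] (< 1e-12) are clamped; larger ones raise,
since they signal inconsistent rates rather than roundoff.  The right-hand
side broadcasts over numpy arrays, so a vector of candidate R-parameters is
integrated in one pass — this is what makes the dense posterior lattice
cheap.

The two solvers are independent routes to the same solution and agree to
better than 1e-6 (observed: ~4e-12 on the dementia world at default
settings); the test-suite also checks the odds route against a test-local
fine-step integration of the *linear odds ODE*, a third route.

## Direct estimator

With surveys at t ± ΔT/2, the directional derivative is the central
difference [p₂(a + ΔT/2) − p₁(a − ΔT/2)]/ΔT, and the midpoint prevalence is
the mean of the two endpoint values — both choices are second-order in ΔT,
and the observed convergence of the estimated R is indeed ~ΔT².  Endpoint
prevalences are interpolated linearly in age; extrapolation beyond a survey
grid is refused and the affected midpoint ages are reported as excluded,
never silently dropped.  Midpoint prevalences of exactly 0 or 1 make the
inversion formula undefined; such ages are flagged (NaN plus a reason) and
kept in the output.  Negative Δm estimates are reported with a warning but
not clipped: they are legitimate diagnostics for noise or protective
associations.  No smoothing of noisy inputs and no confidence intervals are
provided; the estimator is designed for exact or very-large-n prevalence
tables.

## Bayesian estimator

The estimable object is the pair (R(50), R(90)) of a rate ratio whose log is
affine in age between the anchors (extended linearly outside them).  Inputs:
an initial cross-section (the PDE initial condition), a later observed
cross-section with group sizes nⱼ, plus incidence and general-mortality
surfaces treated as known.  For each candidate pair, every compared age a is
projected back along its characteristic to the initial time (launch age
a − ΔT, initial prevalence interpolated linearly; launch ages off the
initial grid are excluded and reported), then integrated forward in the
(m, R) form.  The likelihood is Gaussian with fixed diagonal covariance
Σ = diag(pⱼ(1−pⱼ)/nⱼ).  The pⱼ in Σ are the *observed* target prevalences:
this keeps Σ constant across candidates, making the likelihood a proper
fixed-covariance Gaussian rather than one whose normalization shifts with
the parameters.  Observed prevalences of exactly 0 or 1 degenerate Σ and
raise, naming the offending age.

Two priors are built in: independent uniforms R(50) ~ U(2, 9),
R(90) ~ U(1, 2) (the default, weakly informative), and a bivariate normal
(mean (5.5, 1.5), SDs (1, 0.1), correlation 0.9) for sensitivity analysis.
With exact synthetic data at nⱼ = 10⁶ the two give MAPs differing by well
under 2 % — the likelihood dominates at realistic claims-data sample sizes.

The posterior is evaluated on a deterministic dense lattice (default
141 × 101 over the uniform box; two smooth parameters need no MCMC).
Summaries:

* **MAP** — lattice argmax refined by one-dimensional quadratic
  interpolation in each coordinate (skipped at box edges or where the local
  curvature is not concave).
* **95 % credible intervals** — equal-tailed marginal intervals.  Node
  masses use trapezoid quadrature weights; marginal quantiles invert the
  piecewise-linear CDF through the node densities.  This convention is exact
  for the flat case (a uniform box yields [2.175, 8.825] × [1.025, 1.975])
  and grid-consistent otherwise.  When the posterior is much narrower than a
  grid cell (very large nⱼ) the interval resolution is grid-limited; refit
  on a window around the MAP in that regime (the width-scaling tests do
  exactly this).

## Synthetic worlds

`dementia_scenario` emulates dementia in European women around calendar year
2000: m₀(t, a) = exp(−10.7 + 0.1a + t ln 0.99) with t in years since 2000
(Gompertz–Makeham with a 1 %/year secular decline; ≈0.025/year at age 70),
and R(a) log-linear through (60, 3.0) and (95, 1.5), i.e. R(75) = 2.229,
R(90) = 1.656.  The default incidence i(a) = exp(−16 + 0.15a) — ≈1.9/1000
person-years at 65, doubling roughly every 4.6 years — is a configurable
stand-in with the literature's order of magnitude, not a surveyed rate; the
direct estimator's accuracy pattern is insensitive to this choice because
the finite-difference error is driven by the smoothness of p, not by the
incidence level.

`diabetes_like_scenario(r50, r90, seed_prevalence_level)` builds a type-2-
diabetes-like world over ages 50–90 for exercising the Bayesian machinery:
the same Gompertz–Makeham m₀, incidence rising as e^(0.07a) with its scale
calibrated by deterministic root finding so the 2009 prevalence at age 70
equals `seed_prevalence_level` (default 0.15, in the range reported for
older German men), and R anchored at the requested (r50, r90), which must
lie in the priors' support.  The implied general mortality is provided by
`ScenarioGeneralMortality`, which reconstructs p along each birth cohort
(one cached characteristic solve per cohort) and returns p·m₁ + (1−p)·m₀ —
exactly consistent with the scenario, so parameter recovery is limited only
by solver tolerance.

What the generator deliberately does **not** emulate: sampling noise
(available separately as `sample_observed_prevalence`, pure binomial),
misclassification, migration, cohort effects in incidence, or reporting
delays.  Passing tests therefore demonstrate the estimators' mathematical
correctness and their discretization error under smooth rates — not
robustness to the measurement pathologies of real claims data.

## Problem sizes

The bundled validation uses cross-sections on 7–41 ages, ΔT sweeps over
{0.1, 0.5, 1, 3, 5, 10} years, posterior lattices from 21 × 21 to 141 × 101,
and group sizes 10⁴–10⁸; the full suite runs in about a minute, and the
acceptance script in seconds.

## Known limitations

* Closed-population assumption: no migration adjustment is implemented.
* The direct estimator's error grows roughly quadratically in ΔT; beyond
  ΔT ≈ 3 years only the oldest ages stay within a few percent.
* Group-size columns enter only through the likelihood covariance; absolute
  compartment counts H and I are never modelled.
* Tabulated rate inputs are treated as time-constant (mid-period values);
  strong secular trends over the inter-survey interval are not represented
  unless the user supplies a time-dependent surface programmatically.
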
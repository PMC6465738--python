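# fcrnkinetics

Mechanistic modelling and parameter identification for **FcRn-mediated
recycling of endogenous IgG** in humans.

Circulating IgG owes its unusually long half-life (~23 days) to the neonatal
Fc receptor (FcRn): plasma IgG taken into endosomes by pinocytosis is either
bound by FcRn and recycled back to plasma, or degraded in lysosomes.  Because
the receptor pool saturates, the fractional catabolic rate (FCR) of IgG rises
with its plasma concentration — a nonlinearity that matters clinically
wherever plasma IgG departs far from normal, most prominently in IgG multiple
myeloma.  This package is for modellers and pharmacometricians who need a
*parameterized* human model of that system and an honest account of which
parameters the available human data can actually pin down.

## The model

Quantities (μmol) of IgG in plasma (x₁), peripheral tissue (x₂), unbound in
endosomes (x₃) and bound to FcRn (x₄):

    ẋ₁ = −(k₂₁+k₃₁)x₁ + k₁₂x₂ + k₁₄x₄ + I(t)
    ẋ₂ = k₂₁x₁ − k₁₂x₂
    ẋ₃ = k₃₁x₁ − k₀₃x₃ − (k_on/v₃)x₃(R_tot−x₄) + k_off x₄
    ẋ₄ = (k_on/v₃)x₃(R_tot−x₄) − (k₁₄+k_off)x₄

with synthesis input I(t) (μmol/day).  Around this sit:

* **Tracer experiments** — coupled simulation of a radiolabeled dose plus the
  endogenous pool, the linearized tracer model (effective binding rate
  k₄₃ = k_on(R_tot−x̂₄)/v₃, k₃₄ = k_off), its modal solution
  xᵢ(t) = Σⱼ Aᵢⱼ e^{λⱼt}, and the tracer FCR with its late-time plateau
  FCR_T∞ = k₀₃·A₃₄/A₁₄.
* **Structural identifiability** — the transfer-function coefficient map
  Φ(θ) ∈ ℝ¹⁴ of the linearized model (all 7 rates are uniquely identifiable
  from ideal timecourse data), and the steady-state FCR curve, from which
  only **k₃₁**, **ψ₁ = k₀₃v₃(k₁₄+k_off)/k_on** and **ψ₂ = k₁₄R_tot** are
  identifiable:

      FCR_E(x₁; ψ) = [k₃₁x₁ − ψ₁ − ψ₂ + √(k₃₁²x₁² + 2k₃₁x₁(ψ₁−ψ₂) + (ψ₁+ψ₂)²)] / (2x₁)

* **Estimation** — multi-seed differential evolution for the timecourse model
  (exposing *practical* non-identifiability: near-identical fits, wildly
  dispersed rate estimates) and positively-constrained least squares with
  asymptotic SEs/CIs for the ψ-parameterized FCR curve.
* **Synthetic data** — noisy tracer timecourses and 41-subject FCR cohorts
  generated from lognormal between-subject parameter variability, plus the
  full 100-cohort recovery study (bias and variability of ψ̂).
* **Clinical simulation** — a 70-member parameter ensemble spanning orders of
  magnitude in the endosomal parameters while holding (k₃₁, ψ₁, ψ₂) fixed,
  simulated under a myeloma-therapy synthesis input
  I(t) = (I₀−I∞)e^{−k_kill t} + I∞, and a reduced two-compartment model whose
  elimination is the FCR curve itself.

## Worked example

```python
from fcrnkinetics import (literature_parameters, steady_state, linearize,
    fcr_tracer_asymptotic, make_population_params, generate_fcr_cohort,
    fit_fcr_curve)
from fcrnkinetics.synthetic import PopulationSpec
from fcrnkinetics.tracer import REFERENCE_PSI

params = literature_parameters()          # Table of literature rate constants
ss = steady_state(params, 15.0)           # normal synthesis, 15 μmol/day
print(f"steady-state plasma IgG: {ss.x1_hat:.1f} umol "
      f"(~{ss.x1_hat * 0.15 / params.v1:.1f} g/l)")
theta = linearize(params, 15.0)
print(f"effective binding rate k43: {theta.k43:.1f} /day")
print(f"tracer FCR plateau: {fcr_tracer_asymptotic(theta):.4f} /day")

pop = make_population_params(REFERENCE_PSI)   # population consistent with ψ̂
cohort = generate_fcr_cohort(PopulationSpec(median_params=pop, seed=42))
print(fit_fcr_curve(cohort).summary().round(4))
```

prints

```
steady-state plasma IgG: 469.5 umol (~24.3 g/l)
effective binding rate k43: 291.9 /day
tracer FCR plateau: 0.0320 /day
      estimate       se  ci95_lo  ci95_hi
k31     0.1459   0.0132   0.1191   0.1727
psi1   10.1664   8.5017  -7.0444  27.3772
psi2   18.8415  11.4138  -4.2644  41.9475
```

A healthy subject at normal synthesis holds ~470 μmol IgG in plasma and
turns over ~3.2% of it per day.  The synthetic 41-subject cohort recovers
the pinocytosis rate k₃₁ precisely (±0.013/day) while ψ₁ and ψ₂ carry much
larger uncertainty — exactly the pattern that motivates treating only
(k₃₁, ψ₁, ψ₂) as estimable from FCR data.

A command-line pipeline mirrors the library
(`fcrnkinetics --help`: `simulate-tracer`, `synth-timecourse`,
`synth-cohort`, `fit-timecourse`, `fit-fcr`, `identifiability`,
`recovery-study`, `clinical-sim`); every stochastic run writes a manifest
with its seeds.

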
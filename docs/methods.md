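# Methods

## Model and assumptions

The four-compartment model treats IgG as a single homogeneous species
(no subclass differences) exchanging between plasma, a lumped peripheral
space, and intracellular endosomes where it competes for a fixed total FcRn
pool `Rtot`.  Binding is mass-action with association constant `kon` acting
on the endosomal concentration (hence the lumped ratio `kon/v3`, called
`binding_ratio` throughout to avoid clashing with the transfer-function
coefficients φ₁…φ₁₄).  FcRn synthesis and turnover are not modelled; the
receptor pool is conserved.  All states are quantities in μmol; rate
constants in day⁻¹.  The peripheral volume `v2` is carried in the parameter
type for completeness but enters no equation, and no literature value
exists for it; it is left unset.

For constant synthesis `I0` the model has a closed-form equilibrium with
`x̂3 = I0/k03`, `x̂2 = (k21/k12)·x̂1` and a bound pool `x̂4 < Rtot` for any
finite `I0`.  Stability is assessed numerically — eigenvalues of the
analytic Jacobian at the equilibrium — rather than symbolically; every
random positive parameter draw tested produces a strictly stable spectrum,
and the suite asserts this property on 100 draws per run.

## Tracer experiments

Tracer and endogenous IgG obey the same kinetics and interact only through
the shared free-receptor pool `Rtot − x4,T − x4,E` (8-state coupled system).
For doses small against the endogenous pool, freezing the endogenous system
at equilibrium yields a linear 4-state tracer model with `k34 = koff` and
`k43 = kon(Rtot − x̂4)/v3`.  At the literature parameter values with
synthesis 15 μmol/day, the linear model tracks the nonlinear one within 1%
over 25 days for a 1 μmol dose (≈200× a typical tracer dose) and fails
visibly at 100 μmol; both regimes are tested.

The linear model is solved by eigendecomposition (modal solution), which is
exact, fast enough for optimization loops, and cross-checked against stiff
ODE integration to 1e-8.  Near-coincident eigenvalues (relative gap below
1e-10) raise a degeneracy error advising a parameter perturbation rather
than returning silently inaccurate amplitudes.

The tracer FCR is computed in two algebraically identical forms
(`k03·x3T/x1T` and `−ẏ2/y1`) as an internal consistency check.  Its
late-time plateau uses the slowest mode: `FCR_T∞ = k03·A34/A14`.  The
"experiment end" alternative evaluates `FCR_T(t_N)` at `t_N = 14` days; the
plateau is reached to within ~2% by then at literature-like parameters.

The steady-state (endogenous) FCR as a function of plasma quantity is the
positive root of a quadratic; both the full-parameter form and the
identifiable `(k31, ψ1, ψ2)` form are implemented and agree to 1e-9 on
random draws.  The root is evaluated with the cancellation-free (Citardauq)
branch where the linear coefficient is positive; the textbook branch loses
~6 significant digits when `ψ2 ≫ k31·x1`.

## Structural identifiability

*Timecourse outputs.*  The 14 transfer-function coefficients Φ(θ) were
derived symbolically from the state-space realization and implemented as
explicit polynomials; the structural equalities (φ₄=φ₁₁, φ₅=φ₁₂, φ₆=φ₁₃,
φ₇=φ₁₀=φ₁₄) are asserted over random draws, and the polynomials are checked
against a numeric adjugate/characteristic-polynomial oracle at 50 random
points.  Local identifiability is decided by the rank of ∂Φ/∂θ computed in
**exact rational arithmetic** (sympy): at generic points with rates spanning
five decades the true Jacobian conditioning can exceed 1e12, where no
floating-point singular-value threshold can distinguish "tiny" from
"structurally zero".  Exact elimination gives rank 7 at every generic point
tested and rank 5 when `k31 = 0` disconnects the endosomal chain.

Global uniqueness is probed two ways.  A symbolic polynomial solve of
Φ(θ) = Φ(θ₀) is attempted when requested (capped at 60 s via an alarm
guard); the default is multi-start numerical root finding over
log-parameters (Levenberg–Marquardt from ≥100 log-uniform starts).  The
report distinguishes the two: `globally_unique=True` from the multi-start
route means *no counterexample found among all converged starts*, recorded
with `certified_symbolically=False`.

*FCR-curve outputs.*  The curve's quadratic coefficients depend on the six
physiological parameters only through `(k31, ψ1, ψ2)`; the Jacobian of that
map has rank 3 (no further combinations are identifiable), and curves from
parameter vectors differing only along the unidentifiable manifold agree to
1e-12 in sup-norm.

## Estimation

*Timecourse fit.*  Unweighted least squares over both outputs, minimized by
differential evolution (rand/1/bin, scaling factor 0.5, crossover 0.9,
population 70, up to 5000 generations, one independent run per seed).  Two
numerical choices depart from a naive setup, both forced by measurement:

1. **The search runs over log-rates** (default box 1e-6–1e6 day⁻¹ per
   rate).  A uniform population on a linear box of that width never finds
   optima at rates of order 0.1–300: almost the entire box maps to y ≈ 0
   and the cost surface is flat there.  Log-scaling reflects the
   multiplicative physiology and makes the basin reachable; positivity is
   intrinsic.
2. **Each run's best point is refined by trust-region least squares**
   (bounded TRF on the residual vector), which exploits the least-squares
   structure far better than a generic quasi-Newton polish.  With it, every
   seed reaches J below 1e-6 per observation on dense noise-free data.

On a realistic design (≈15 samples per output, additive noise SD 0.01),
ten seeds return RMSEs identical to three significant figures while the
endosomal rates disperse with CV up to ≈3 — the practical-non-identifiability
signature that motivates the FCR-curve route.  Runs are deterministic given
(data, settings, seed).

*FCR-curve fit.*  Positively-constrained least squares (TRF, start
(1, 1, 1)); standard errors from the asymptotic covariance σ̂²(JᵀJ)⁻¹ with
σ̂² = RSS/(n−3), 95% intervals from the t(n−3) quantile.  A singular
normal-equations matrix (e.g. a flat curve sampled only at tiny plasma
quantities) yields no SEs and an `ill_conditioned` flag.  Coverage of the
95% intervals is verified empirically: over 200 synthetic cohorts with
i.i.d. Gaussian FCR noise (SD 0.01 day⁻¹, roughly the historical cohort's
scatter), per-parameter coverage lies in the 90–98% band.

*Recovery metrics.*  Bias `b = μ − p` and variability `v = (s.d.² + b²)/p`
are implemented as defined.  The companion root form `√(s.d.² + b²)/p` — a
relative RMS error — is tabulated alongside (`variability_rms`) because the
two conventions circulate interchangeably in the estimation-assessment
literature and only the root form is dimensionless.

## Synthetic data

The generators define the study conditions; real historical data (digitized
from published figures) are not redistributable and are not emulated beyond
their statistical shape.

*Timecourses* add i.i.d. Gaussian noise (default SD 0.01, truncated at 0)
to linear-model retention curves; the t = 0 points stay at 1.0 (the dose is
known).  The true error structure of 1960s radio-assays is unknown; the
additive-Gaussian choice is an explicit stand-in, so tests passing under it
show estimator correctness under that noise model, not robustness to the
historical assays' counting statistics or urine-collection artifacts.

*FCR cohorts* draw each subject's parameters lognormally (median = the
population values, log-scale SD 0.2 on {k21, k12, k14, k03, koff, k31,
Rtot, kon/v3}) and a synthesis rate log-uniform on 2–400 μmol/day, spanning
hypogammaglobulinemia to myeloma-range plasma IgG.  The measured FCR is the
tracer plateau FCR_T∞ by default — what the historical protocol estimates —
with finite-time and exact-endogenous alternatives.  The 0.2 log-SD
produces scatter of the magnitude seen in the historical 41-subject cohort
and is configurable; subjects whose draw is unstable or modally degenerate
are redrawn and counted.  FCR rises with plasma IgG in every generated
cohort (saturable salvage), with Spearman correlation well above zero.

The full recovery study (100 cohorts × 41 subjects, fit each, summarize) is
reproducible bit-for-bit from a master seed via spawned child streams, and
reproduces the characteristic ≈5% upward bias in k31 (mean estimate ≈0.16
against a generating 0.154): the fit applies the endogenous steady-state
curve to tracer-derived FCR values, which sit slightly above it.

## Clinical ensemble and reduced model

Ensemble members fix three of {k03, Rtot, koff, k14, kon/v3} to lognormal
draws (σ = 1 on the log scale, medians at the literature values — "several
orders of magnitude" of spread across 70 draws) and solve the two ψ
identities for the rest; triples containing both Rtot and k14 would
over-determine ψ2 = k14·Rtot and are excluded, leaving 7 of the C(5,3) = 10.
Draws forcing a negative solved parameter are rejected and redrawn.  With
σ = 0 the construction degenerates to a single vector only if the medians
themselves satisfy the ψ identities; with inconsistent medians each triple
completes differently (both cases are tested).

Simulations start from the pre-treatment steady state at I(0) = I₀ (the
plasma and peripheral components of which depend on the parameters only
through ψ, so all members share x1(0) and x2(0)) and run 150 days at 0.25-day
output resolution — with k_kill = 0.055 day⁻¹ the synthesis transition is
~98% complete by day 70.  BDF with the analytic Jacobian at rtol 1e-10 /
atol 1e-12; the endosomal rates make the system stiff.

The reduced two-compartment model replaces the endosomal subsystem by the
elimination function f(x1) = FCR_E(x1; ψ) — a quasi-steady-state assumption
valid while synthesis changes slowly against endosomal turnover.  The
four-compartment equations' recycling flux `k14·x4` has no counterpart
state in the two-compartment system; the reduced model is therefore written
*without* it, since f(x1) already nets recycling against loss.  Its
self-consistent initial state solves f(x1)·x1 = I(0) and coincides with the
full model's plasma/peripheral steady state.

**Sampling variability of the ensemble-spread statistic.**  The headline
comparison — the maximal pairwise relative difference in x1(t) over time and
over all 70 members — is the maximum of a heavy-tailed draw: it is dominated
by whichever member happens to combine slow endosomal relaxation (small
k03 + k43 or k14 + koff) with the mid-transition synthesis change, where the
quasi-steady-state approximation is weakest (the spread peaks near day 50–60
and vanishes at both ends).  Across master seeds this maximum realizes
between roughly 0.14% and 0.47% under identical generation settings; a
single realization near 0.2% is typical but not guaranteed.  The
reduced-model-versus-members maximum behaves identically (the reduced
trajectory sits near the ensemble's center).  Increasing k_kill tenfold
weakens the quasi-steady-state premise and grows the discrepancy
monotonically.

## Numerical defaults

| Quantity | Default | Why |
|---|---|---|
| ODE tolerances (oracle) | rtol 1e-10, atol 1e-12 | reference-grade trajectories |
| ODE tolerances (routine) | rtol 1e-8, atol 1e-10 | 100× faster, visually identical |
| Modal degeneracy gap | 1e-10 relative | below it, amplitudes are unreliable |
| FCR_T series floor | x1T > 1e-12·D | guards the ratio at extreme decay |
| DE bounds | 1e-6–1e6 day⁻¹, log-scaled | covers all plausible rates; positivity |
| Experiment end t_N | 14 d | plateau reached to ~2% |
| Cohort log-SD | 0.2 | historical-cohort-like scatter |
| Synthesis range | 2–400 μmol/day, log-uniform | clinical span of plasma IgG |
| Ensemble log-σ | 1.0 | orders-of-magnitude parameter spread |

## Known limitations

* The timecourse DE fit recovers the *fit*, not necessarily the generating
  rates: discretely-sampled retention data admit near-equivalent basins
  whose residuals differ below the sampling resolution.  This is the
  practical-non-identifiability phenomenon the package exists to expose,
  but it means DE point estimates of the endosomal rates should never be
  interpreted physiologically.
* Concentration↔quantity conversion assumes a single molar mass
  (150 kg/mol) and a fixed plasma volume; both are configurable but
  per-subject volumes are not modelled.
* The multi-start global-uniqueness check can refute but not certify
  uniqueness; certification requires the (optional, time-capped) symbolic
  route.
* Urine-activity modelling, whole-body counting corrections, FcRn turnover
  and multi-organ structure are out of scope.
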
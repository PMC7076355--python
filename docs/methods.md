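# Methods

## Model structure and assumptions

The package couples a two-compartment plasma model of oxaliplatin to two
toxicodynamic (TD) observables measured in rats over a four-week weekly
dosing schedule.  Doses are IV boluses expressed per kg body weight, so
with the central volume also per kg (mL/kg) all concentrations are
weight-free and body weight is not a covariate.  Elimination is linear
(the underlying in-vivo data show dose-proportional AUC), and only
single-dose kinetics are modelled: the plasma accumulation that real rats
show after the fourth weekly dose is deliberately out of scope, so every
dose event contributes an identical superposed bi-exponential.

The acute observable (acetone-test withdrawal count) is the sum of a
drug-driven indirect-response state and an analytically added habituation
term `x0·exp(−k_handling·t)` describing control animals that get used to
handling.  The equations admit a second reading in which the handling term
is itself integrated inside the turnover equation; the additive reading is
used because the baseline condition `x_acute(0) = Handling(0) = x0` then
holds exactly with `Response(0) = 0`.  No ceiling is imposed on the score:
the assay's definition (mean withdrawal count over six stimulations) hints
at an upper bound, but none is stated, and the fitted dynamics stay well
below any plausible one.

The chronic observable (von Frey threshold) is the terminal state of a
five-stage transit chain, giving the weeks-long onset delay seen in
mechanical allodynia.  Tying the loss rate to the baseline, `kout =
kin/x0`, makes the drug-free chain a fixed point at `x0 = 8 g`; all six
states are initialised there, because any other initial condition would
produce a drug-free transient that control animals do not show.  With the
reference `Emax = 168`, the inhibition factor `(1 − Emax·H)` is strongly
negative near Cmax and the chain states — and at higher doses the predicted
threshold itself — transiently go negative.  The chain is linear and is
integrated exactly as written; a reporting-only clamp at zero
(`clamp_nonnegative=True`) is available for display, and deliberately never
touches the integrated states, since clamping would alter the dynamics the
parameters were estimated under.

Fixed constants (not estimated): acute `x0 = 3.1` times, `k_handling =
0.08 /day`, `γ = 6`; chronic `x0 = 8 g`, `n = 5` stages, `γ = 4`.

## Time units and integration

PK rate constants are per hour, TD constants per day.  The coupled system
integrates on a single day-scale clock; `ke, k12, k21` are multiplied by 24
once, at simulation time.  The drug pulse decays on an hours scale (terminal
half-life ≈ 1.2 h) inside a 28-day horizon, and the Hill drive with γ = 4–6
switches on/off within ~0.05 day of the concentration crossing EC50, so the
integrator must resolve a sharp pulse after every dose.

Two engines are provided:

* `method="grid"` (default): between dose events every state equation has
  the form `dx/dt = f(t) − k·x`; it is advanced with an exact exponential
  step under piecewise-linear forcing, on a dose-anchored grid that is
  geometric after each bolus (first step 1e-6 day, 512 nodes per inter-dose
  segment).  The scheme preserves the drug-free steady state to machine
  precision (hence the exactly flat placebo von Frey trajectory) and
  converges at second order: halving the node spacing reduces the error
  ×4, with worst-case absolute error ≈ 2e-3 g against the reference
  solution at the default density.
* `method="ode"`: adaptive LSODA (rtol 1e-8, atol 1e-10) restarted at every
  dose time.  This is the independent numerical cross-check; the test suite
  asserts grid/ODE agreement.

The grid engine is ~50× faster and is what the estimation loops use; per
regimen the grids and concentrations are precomputed once
(`GridExposure`) and reused across objective evaluations.

## Synthetic cohorts

The generator emulates the original study design: PK arm — 15 rats, 5 per
dose group (3/5/8 mg/kg single bolus), plasma sampled at
3/5/10/20/30/45/60/90/120 min; TD arm — 21 distinct rats (control n = 6,
three dosed groups n = 5), weekly dosing on days 0/7/14/21, both tests on
days {2,4,7,9,11,14,16,18,21,23,25,28} (a Mon/Wed/Fri approximation; the
study gives weekdays, not day numbers).  Inter-individual variability is
lognormal with `ω = %CV/100` taken directly as the log-scale SD (the
first-order convention dominant in pharmacometrics; the exact-lognormal
alternative `sqrt(ln(1+CV²))` is available via
`omega_parameterization="lognormal_exact"` and differs by ~15% at the
largest reference ω of 91%).  Residual error is proportional for plasma
concentration (21.9%) and acetone score (32.1%), additive for the von Frey
threshold (1.3 g).  Negative simulated observations are kept, not redrawn:
truncation would bias the estimator-recovery experiments (a
`truncate_negative` flag exists for realism studies).  Per-arm, per-animal
seed streams (`SeedSequence([seed, arm, animal, purpose])`) make tables
bit-reproducible and keep the two arms independent.

What the generator does *not* emulate: the multiple-dose PK accumulation,
assay detection limits and rounding (von Frey filaments are a discrete
ladder; the generator is continuous), dropout, and day-of-week effects.
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions, not robustness to these real-data features.

## Estimation

The architecture is two-stage: PK first, then each TD model with PK fixed
at typical values (the TD animals have no concentration data, as in the
study).  All objectives are extended least squares (ELS) −2 log
likelihoods with the error scale profiled at its conditional MLE; searches
run on log parameters (positivity by construction) with multi-start
Nelder-Mead (5 starts, ×/÷2 perturbations, relative function tolerance
1e-6), and asymptotic CV% come from the finite-difference Hessian at the
optimum (`cov = 2·H⁻¹`; on the log scale the SE is directly the relative
SE).  Proportional variances use `max(|f|, 1e-6·dose/V)` to avoid
blow-ups near zero predictions.

**PK population fit.**  Three methods are provided.  Plain standard
two-stage (`method="two_stage"`: per-animal ML, geometric-mean fixed
effects, ω from the SD of log estimates) and naive pooling
(`method="pooled"`) are both available but measurably biased on this
design: nine samples over two hours weakly separate `ke/k12/k21`, individual
fits wander along a likelihood ridge (occasionally into a spurious
ultra-fast disposition phase, which is why individual fits screen their
Hessian CV% and flag runaway estimates), and the biases do not average out.
The default is therefore an iterative two-stage estimator
(`method="its"`, in the Steimer global-two-stage family): per-animal ML
fits give starting values; three EM-like iterations then refit every
animal by empirical-Bayes MAP under a diagonal lognormal population prior,
update the population centre by the median of the individual deviations,
and re-estimate each ω as deviation variance plus mean posterior variance
(so shrinkage does not collapse the prior).  On 20-cohort recovery
experiments this brings all four fixed effects within ~±10% of the
generating values; `k21` (ω = 91%CV) remains the least stable quantity,
consistent with the wide bootstrap interval the original analysis reported
for it.

**Acute TD fit.**  Pooled ELS with proportional error over
(kin, kout, Emax, EC50); no random effects (the study found acute-model
etas fully shrunk).  A dataset without drug exposure is rejected as
unidentifiable unless Emax/EC50 are frozen (freezing `Emax=0` fits the
control habituation curve alone).

**Chronic TD fit.**  Stage 1: pooled ELS with additive error over
(kin, Emax, EC50), `kout` always derived as `kin/x0`.  Stage 2: per-animal
refits of (kin, EC50) with Emax frozen; ω%CV is the SD of the per-animal
log deviations, computed over treated animals only — the placebo
prediction is flat at `x0` for *any* kin, so control animals carry no
random-effect information and would spuriously shrink ω.  The reported
residual SD `sigma_add` is the degrees-of-freedom-adjusted RMS residual
around the stage-2 individual predictions (`N − 2` per refit animal):
stage-1 pooled σ also absorbs the inter-individual variability and
overstates the residual error (it is kept in `extra["sigma_stage1"]`).  A
final empirical-Bayes pass (prior = estimated or supplied ω) produces
shrunken deviations for shrinkage diagnostics.

Structural-model selection follows the study's criteria: non-nested models
need an AIC drop ≥ 2; nested models need a −2LL drop ≥ 6.63 per added
parameter.

Search bounds: TD fits constrain each log parameter to ±ln 50 around the
initial value; an optimum pinned at that bound is flagged non-converged.
This matters in practice: when the TD animals carry PK variability that the
typical-PK fit ignores (the generator's realistic default,
`pk_iiv_in_td=True`), the pooled likelihood can genuinely prefer a
degenerate regime with EC50 → 0 (drug effect "on" whenever drug is
present).  Recovery experiments therefore generate TD cohorts with
`pk_iiv_in_td=False`, matching the estimator's assumption, and real-data
users should treat a bound-pinned fit as a model-mismatch diagnostic, not
an estimate.

## Qualification tools

*pcVPC* — observations and model simulations are prediction-corrected by
the ratio (proportional endpoints) or difference (additive von Frey
endpoint) between the bin-median and record-level population prediction;
bins are the nominal design times pooled across dose groups (the point of
the correction; `stratify="group"` keeps groups separate, in which case
the correction is a no-op under this balanced design).  5th/50th/95th
percentiles of the corrected observations are compared with the median and
95% band of the same percentiles across simulated replicates.  The band
estimates the percentile's sampling distribution, so its width is roughly
independent of the replicate count; what improves with `n_sim` is the
Monte-Carlo error of the plotted lines (~1/√n_sim), which is what the test
suite checks.

*Bootstrap* — animals are resampled with replacement within dose-group
strata (preserving group sizes) and refitted; medians and percentile
intervals (5–95 or 2.5–97.5) are reported, with non-converged replicates
counted, excluded, and the result flagged unstable above 20% failures.

*GOF diagnostics* — IWRES `(y − IPRED)/sd(IPRED)` plus summary statistics.
A FOCE-style CWRES is not computed because the estimator is not FOCE;
residual tables label exactly what they contain.

*η-shrinkage* — `100·(1 − SD(η̂)/ω)`, undefined (NaN) at ω = 0, computed
from the empirical-Bayes deviations where available.

## Problem sizes and defaults

Recovery experiments use 20 replicate cohorts per arm with the original
cohort sizes (15 PK / 21 TD rats) — enough for the median's Monte-Carlo
error to sit well inside the assessment tolerances while a full run stays
in the minutes range on one CPU.  The replicate-seed lists derive from a
single master seed.  Scenario simulations default to a 0.05-day output
grid over 28 days.  Bootstrap and VPC default to 1000 replicates
(overridable; the test suite runs them at reduced counts).

## Known limitations

* `k21` recovery is marginal by construction: with ω = 91%CV and 15
  animals, the 20-cohort median has ~6–7% sampling error before any
  estimator bias, and ML-type estimates of `k21` are positively skewed
  (the parameter is confined to (β, α) and both edges are likelihood
  degenerate).
* The chronic `EC50` pooled estimate inherits the full spread of its 28%CV
  random effect; individual 20-cohort medians scatter by ±10–18% between
  seed sets.
* Typical-PK TD fitting under strong unmodelled PK variability can prefer
  a degenerate low-EC50 optimum (flagged, see above).
* The model is a rat model with total-platinum plasma concentrations; no
  claim is made for clinical ordinal-grade neuropathy scales, infusion
  administration, or the multiple-dose accumulation phase.
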
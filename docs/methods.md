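# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish. It is the package's own account; all numbers
quoted here are computed by the code (tests or the acceptance script).

## Structural model

Both analytes follow one-compartment disposition with first-order oral
absorption. The oral dose splits at the liver: a fraction `fpm` enters the
metabolite path pre-systemically, `1 - fpm` is absorbed into the parent
compartment at rate `ka` (after an optional lag `tlag`). The parent is
eliminated at `(clp + clpm)/vp`, of which `clpm/vp` is conversion flux into
the metabolite compartment; the metabolite is eliminated at `clm/vm`. All
clearances and volumes are apparent (`/Fp`, `/Fm`): with oral data only,
bioavailability is structurally confounded and is never estimated
separately. Consequences worth keeping in mind:

* absolute bioavailability is out of reach by design;
* no molar-mass correction is applied between parent (298 g/mol) and
  metabolite (314 g/mol): concentrations are modelled in measured ng/mL and
  the apparent metabolite scale `Fm` absorbs any constant factor.

The first-pass-formed metabolite is placed in the depot and absorbed with
the same `ka` as the parent. A single depot feeding both compartments is
the standard parent–metabolite construction when the metabolite's input
kinetics are unobserved; an instantaneous-bolus alternative is available as
`metabolite_input="bolus"` and changes only the early metabolite phase.

Everything is closed form. Each amount term is an inverse Laplace
transform of `1/Π(s + k_i)`; repeated eigenvalues (e.g. `ka = ke`) are
evaluated by the analytic limit expressions, switched at a relative
closeness of 1e-9, so profiles are finite for every admissible parameter
set. The closed forms are verified against `scipy.integrate.solve_ivp` at
1e-6 relative tolerance over random parameter sets.

Units: rat parameters are per kg with doses in mg/kg; human parameters are
totals with doses in mg; concentrations are always ng/mL. The single
mg/L → ng/mL factor (1000) is applied at exactly one point
(`structural.profile_arrays`).

Derived metrics: `ke = (clp + clpm_eff)/vp`, `t1/2 = ln 2/ke`,
`AUC_tau,ss = (1 - fpm_eff)·dose/(clp + clpm_eff)` (interval-independent
under linearity and equal to single-dose AUC0–∞). Cmax/Tmax are located on
the analytic profile by a 256-point coarse grid followed by bounded
golden-section refinement (xatol 1e-6 h); the grid step guards against the
local minimum that a lag time introduces at the start of a steady-state
interval. Steady state itself is evaluated by superposing enough doses
that the oldest contributes < 1e-10 relative, which matches the analytic
accumulation limit to well below reporting precision.

## Propolis covariate

PPL enters as a static dose covariate (no PPL kinetics) through
`1 - emax·D/(D + ic50)` factors on `fpm` and `clpm`. The factor is 1 at
D = 0, `1 - emax/2` at D = ic50, and `1 - emax` in the limit. For human
simulation the daily PPL dose in mg/day is divided by the 70-kg body
weight to return to the covariate scale on which the inhibition constants
were estimated (mg/kg). This conversion is a documented package
assumption: it is the reading under which the extrapolated interaction
sizes reproduce the reference values, and it keeps the covariate
dimensionally consistent across species.

## Population layer and estimation

Lognormal IIV on a declared subset of structural parameters (final model:
`clp` only, ω = 0.079 ⇒ 7.9% CV; base model additionally `clpm` at 149%),
proportional residual error per analyte (19.9% parent, 24.0% metabolite).
Only a diagonal ω structure is supported; the reference analysis reports
no covariances.

The marginal likelihood uses the conditional (Laplace) approximation: per
subject the joint −2 log-density is minimised over η (Newton iteration
with finite-difference derivatives, step 1e-4, convergence |Δη| < 1e-6,
≤ 50 iterations, steps capped at |Δη| ≤ 4 with step-halving), and the
log-determinant of the conditional Hessian supplies the correction, with
residual variance evaluated at the conditional η (interaction). As ω → 0
this reduces exactly to the naive-pooled −2 log-likelihood, and on
single-subject problems it agrees with adaptive quadrature to well under
one OFV unit (tested at ω from 0.1 to 1.0). Two implementations exist —
a vectorised numpy reference and a numba kernel ~15× faster — and are
cross-checked in the tests; the kernel is used when numba imports.

Outer maximisation is Nelder–Mead on transformed parameters (log for
rates, clearances, volumes, ic50, ω², σ; logit for `fpm` and `emax`),
optionally multi-start with jittered initial vectors. The default is a
single start: with this parameterisation the surface is well behaved, and
in the simulation studies restarts changed nothing but runtime. An
optional `presolve` stage first fits the pooled model (no random effects)
to move the structural and residual parameters cheaply, then refines with
the full likelihood; simulation-study and bootstrap fits use it.  The
covariate search never presolves: its fits start from the current
estimates, which a pooled restart would discard, and on models with large
IIV the pooled stage can steer the fit into an inflated-residual local
optimum whose escape by a more flexible candidate model then masquerades
as a covariate effect.

Standard errors come from the numeric Hessian of the OFV on the
transformed scale (central differences including cross terms, step 5e-3,
inner warm starts reset per evaluation so the objective is
path-independent), covariance `2·H⁻¹`, delta-method back-transform. When
the Hessian is not positive definite — which genuinely happens when
`ic50_fpm` drifts onto its flat ridge, the same weak identifiability the
reference analysis reported as 358% RSE — RSE values are omitted with a
warning rather than reported from a pseudo-inverse. η-shrinkage is
`100·(1 − SD(η̂)/ω)`.

Below-quantification observations (< 5 ng/mL) are dropped from the
likelihood (the simplest defensible policy given a stated calibrated range
and no reported BLQ handling), as are pre-dose records. Above-range values
are flagged but retained.

## Covariate search

Stepwise: forward addition accepts the candidate with the largest OFV drop
while the drop exceeds the χ² critical value at p < 0.05 for the added
degrees of freedom (an Emax+IC50 pair = 2 df ⇒ 5.99); backward elimination
then removes any effect whose deletion costs less than the p < 0.01
critical value. Critical values come from `scipy.stats.chi2`, so
candidates with other df work unchanged. In simulation at the reference
truth, the search keeps the base model on null data at close to the
nominal rate, always finds the (large) `clpm` effect, and finds the
(small, Emax 0.147) `fpm` effect in roughly 55–65% of replicates — the
joint selection probability sits just above one half at this design size
(18 rats), which is the honest power of the published design rather than a
software property.

## Evaluation

* **Bootstrap**: subjects resampled with replacement, stratified by PPL
  group (keeps every replicate estimable; the reference analysis does not
  state its stratification). Replicates refit from the original estimates;
  percentile CIs are order statistics with linear interpolation
  (Hyndman–Fan type 7). Summaries are reported both for usable replicates
  and unfiltered, because the convergence-filter policy is a judgement
  call; a replicate counts as usable when its optimum is finite.
* **VPC**: bins are the exact nominal design times (the design is
  balanced), no smoothing, no quantification-range censoring of the
  simulations; per bin the observed 5/50/95th percentiles are overlaid on
  the simulated 5th–95th prediction band and the 95% CI of the median.
* **GOF**: PRED at η = 0, IPRED at the empirical Bayes η, CWRES from the
  conditional linearisation (residual decorrelated by `JΩJ' + diag(σ²f²)`
  via Cholesky; singular covariance falls back to plain weighted residuals
  with a warning).

## Extrapolation

`V_human = V_rat,per-kg · 70` (allometric exponent fixed at 1.0 for
volumes), `CL_human = CL_rat,per-kg · (21/85) · 70` (liver blood flow rat
85, human 21 mL/min/kg — the appropriate scaling for a drug cleared by
hepatic CYPs, where simple allometry is known to fail), fractions and
inhibition constants unchanged across species, and rat IIV/σ carried over
as identical variances. `ke` follows from the scaled parameters;
`ka` solves the Tmax identity on the `ka > ke` branch with Brent's method
on (ke·(1+1e-6), 1e3), after subtracting the 2-h enteric-coating lag from
the 6-h literature Tmax (both are configuration values). The identity has
no `ka > ke` root once effective Tmax reaches 1/ke; that case raises a
domain error naming the limit. The derived composite scales
(`CL/FDLX = CL/Fp/(1 − fpm)`, likewise for volume) are what published
human estimates are reported on, and the two-fold acceptance check
compares on that scale.

Note on the reference human table: its last two rows carry the same label,
but the second value equals the per-kg metabolite *volume* times 70 kg and
is dimensionally a volume; it is treated as `Vm/Fm` here. Similarly the
prose value of 0.697 1/h for `ka` is inconsistent with the tabulated
0.687, and only 0.687 satisfies the Tmax identity at `ke` = 0.0547; the
package reproduces 0.687.

## Human scenarios

The grid is 40/60 mg, single dose / once daily (τ = 24 h) / twice daily
(τ = 12 h, per-administration dose), PPL 0/5000/15,000 mg/day, 7 days
(steady state is reached after ~3 half-lives ≈ 1.6 days; a warning fires
if a requested duration cannot reach it). Exposure metrics are
model-predicted concentrations: residual assay error is deliberately
excluded, so replicate SDs reflect inter-individual variability only.
Replicate η draws are shared across PPL levels within a scenario row
(common random numbers), so percent differences are not blurred by
simulation noise; with the typical-value option the table is fully
deterministic. Under linear kinetics the table obeys exact invariants
that the tests assert: 60-mg metrics are 1.5× the 40-mg metrics,
steady-state AUC per interval is frequency-invariant, and percent
differences are identical across dose levels.

## Synthetic data

The generator emulates the rat study design: 3 groups × 6 rats, single
oral DLX 40 mg/kg, PPL 0/500/1500 mg/kg, sampling at 0, 0.25, 0.5, 1, 2,
4, 8, 12, 24 h, quantifiable range 5–1000 ng/mL applied as flags (BLQ
below, ALQ above; values are never truncated, except that a proportional-
error draw below −100% — about a 5σ event — is clipped at zero
concentration). The default truth is the reference final model; a base
preset (no covariate, IIV on `clp` and `clpm`) supports covariate-search
experiments. Concentrations are not rounded.

What passing tests on these data show: that the estimation machinery
recovers the generating process it assumes. What they cannot show:
robustness to real-data features the generator omits — model
misspecification, assay rounding and drift, BLQ-censoring informativeness,
body-weight variability, or non-diagonal random-effect structure.

## Problem sizes

The simulation studies use 100 synthetic studies for parameter recovery,
200 bootstrap replicates on one study, and 50 replicates each for the
covariate-search null and power experiments; these sizes give Monte-Carlo
error comfortably below the tolerances they are tested against while
keeping the full suite inexpensive. Production analyses would typically
use 1000 bootstrap/VPC replicates, which the defaults of the library
functions reflect.

## Known limitations

* One-compartment disposition per analyte; no saturable elimination,
  enterohepatic recirculation, or protein-binding model.
* PPL is a static covariate — no PPL concentration-time course, so dose
  timing within a day cannot matter.
* The interspecies step assumes the interaction constants and variability
  are species-invariant; that is an assumption, not an inference.
* FOCE-style conditional approximation, diagonal ω, proportional error
  only; no inter-occasion variability.
* The `ic50_fpm`/`emax_fpm` pair is weakly identified at the rat design
  size; its point estimates should not be over-interpreted (the recovery
  criterion exempts `ic50_fpm` accordingly).
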
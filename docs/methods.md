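# Methods

## The model

`tacropk` implements a hierarchical (population) pharmacokinetic model of
tacrolimus given by continuous IV infusion to pediatric and young-adult
hematopoietic cell transplant (HCT) patients. The structural model is a
linear two-compartment system with zero-order input into the central
compartment; with amounts in µg and volumes in L the central concentration
`C = A1/V1` is in µg/L ≡ ng/ml:

```
dA1/dt = R(t) − (CL/V1)·A1 − (Q/V1)·A1 + (Q/V2)·A2
dA2/dt =          (Q/V1)·A1 − (Q/V2)·A2
```

Intercompartmental clearance and peripheral volume are tied to the primary
parameters by a fixed multiplier: `Q = Fact·CL`, `V2 = Fact·V1`, with
`Fact = 2.0` (fixed; determined in the original analysis from the average
of published tacrolimus models, since a trough-only design cannot estimate
peripheral parameters).

Individual parameters combine fixed effects, allometric weight scaling,
a binary CYP3A4/5-inhibitor covariate (azole antifungal co-treatment) and
log-normal random effects:

```
CL_ij = θ_CL · (WT_i/70)^0.75 · θ_INH^INH_ij · exp(η_CL,i + κ_ij)
V1_i  = θ_V1 · (WT_i/70)^1.0  · exp(η_V1,i)
```

with occasions j defined as 24-h infusion bags (bag j covers
[24(j−1), 24j) hours). Residual error is proportional:
`DV = IPRED·(1 + ε)`, `ε ~ N(0, σ²)`, floored at zero (the floor fires
with probability ~1e−8 per record at the default σ; troughs are far from
zero).

Default parameter values (the estimates the package is built around, used
as simulation ground truth): θ_CL = 4.2 L/h, θ_V1 = 61.9 L, θ_INH = 0.8,
ω_CL = 0.261, π_CL = 0.287 (inter-occasion SD on CL), σ = 0.179.
Variability magnitudes are reported as percent CVs using the convention
`CV% = 100 × SD of the log-scale effect`. The between-subject SD of V1 is
included in the model but its magnitude is not publicly reported; the
package default is ω_V1 = 0.30 (a typical mid-size IIV for volume terms),
configurable everywhere.

The kinetics are solved in closed form: over any span with constant rate
and constant parameters the 2×2 rate matrix is exponentiated through its
eigenvalues (real and distinct whenever Q > 0), and the state is advanced
as `A(t) = A_ss + e^{Mt}(A0 − A_ss)` with `A_ss = (R·V1/CL, Fact·R·V1/CL)`.
Numerical ODE integration (`scipy.integrate.solve_ivp` at rtol 1e−10) is
used only as a test oracle; agreement is ~1e−10 relative. The steady-state
trough is `R/CL` exactly, independent of V1, Q, V2 and Fact — asserted in
the tests by varying Fact.

## The synthetic cohort

No patient-level data are distributed with the study, so the package
generates virtual cohorts with the design's statistical structure:

- n = 111 subjects, 14 daily bags, one trough per bag drawn 15 min before
  the next bag (t = 24j − 0.25 h).
- Weights: truncated log-normal with median 23.9 kg on [5.5, 155.5] kg;
  the log-SD default (0.7) makes the extremes of a 111-subject draw match
  the reported range.
- Starting rate 1.25 µg/kg/h; daily titration toward the 7–10 ng/ml
  window. The clinical adjustment rule is not published, so the generator
  uses: if the trough is outside the window, multiply the rate by
  8.5/trough (the window midpoint over the measurement), capped at ±50%
  change per day, floored at 0.1 µg/kg/h. This reproduces the reported
  qualitative behaviour — supratherapeutic early troughs under fixed
  per-kg dosing and a declining mean rate that plateaus.
- Inhibitor co-treatment: a subject-level contiguous episode from a
  uniformly drawn start day through the end of the record (azoles are
  typically started once and continued), with the subject-level
  probability solved so the expected fraction of INH=1 observations is
  0.117 (the reported 193/1,648).
- Under the defaults every subject has 14 troughs (1,554 records,
  matching the reported 1,648 in scale); an optional geometric censoring
  after a configurable day mimics incomplete records.
- One `numpy` Generator drives a run; per subject the draw order is
  fixed (weight and inhibitor episode at cohort creation; then η_CL,
  η_V1, the κ vector, and one ε per day), so seeded runs are
  byte-identical.

What the generator does **not** emulate: assay quantification limits,
irregular sampling times, dose-recording errors, non-random inhibitor
initiation (confounding by indication), hold/restart of infusions, or any
time-dependence of clearance. Passing recovery tests therefore show the
estimator is consistent for data generated by the model itself — the
usual simulation-estimation standard — not that the model is correct for
real patients.

One point where the generator deliberately deviates from a naive reading
of the source material: the model's own median day-1 (23.75 h) trough at
the median weight is ≈ 8.8 ng/ml, below the 10.2 ng/ml observed median
first trough (first draws in practice occurred 24–48 h after initiation,
and the original VPC notes under-prediction of the day-1 median). The
supratherapeutic tendency appears from day 2 under fixed dosing, and that
is what the tests assert.

## Estimation

The marginal likelihood per subject integrates over d = 2 + J random
effects (J = occasions with an observation; κ's of unobserved occasions
are fixed at the prior mode and excluded). The joint conditional mode is
found by a damped Newton iteration (Gauss–Newton Hessian, central-
difference sensitivities, vectorized across subjects; gradient tolerance
1e−6, zero-restart safeguard against bad warm starts).

For the integral itself three approximations are implemented:

- **`quad` (default): mode-centered quadrature.** The integrand is
  standardized by the conditional mode and the *exact*
  (finite-difference) Hessian of the penalized objective, and averaged
  over a fixed antithetic Sobol rule (1024 nodes, proposal scale 1.3)
  against the exact joint density. This is a deterministic quadrature
  refinement of Laplace's method. The node rule is an algorithmic
  constant, so the OFV is a smooth deterministic function of the
  parameters. Against brute-force reference integration (10⁵ draws per
  subject) the error is ≲ 2 OFV units out of ~7,200 on the study design,
  approximately uniform over parameter space.
- **`foce`**: the classic first-order-conditional-with-interaction
  marginal `−2lnL = ln det V + res'V⁻¹res + n·ln2π` with
  `V = FΩF' + diag(σ²f(b̂)²)`, `res = y − f(b̂) + Fb̂`.
- **`foce_log`**: the same linearization applied to `ln f`, with the
  residual `u = ln(1+ε)` replaced by a Gaussian with u's exact first two
  moments (computed by Gauss–Hermite quadrature), plus the log-transform
  Jacobian term, so OFVs are comparable across methods.

Why the default is not a pure linearization: with one trough per
occasion, the occasion effect κ and the residual ε are separated only by
the state carry-over between days (terminal half-life ≈ 38 h) and by the
curvature of the model, and the linearized marginals distort exactly that
information. On full-design simulated data the exact likelihood (checked
by importance sampling) has its optimum essentially at the generating
values, but `foce` moves the optimum to π ≈ 0.21 / σ ≈ 0.22 (truth
0.287/0.179) and `foce_log` collapses ω_V1 toward 0 — each linearization
misrepresents a different piece of the skewed geometry. The quadrature
method tracks the exact surface and recovers all components. `foce`
remains the right tool for fast likelihood-ratio screening of fixed
effects (used by the covariate search), and both linearizations are kept
tested.

The population fit minimizes the summed OFV with Nelder–Mead over
log-transformed parameters (all estimated quantities are positive;
variabilities are estimated on the SD scale), warm-starting the inner
modes from the previous outer iterate and starting from an initial
simplex of 0.1 log-units (the scipy default collapses to 2.5e-4 for
coordinates starting at zero and can stall). Default outer tolerances:
fatol 1e−3, xatol 1e−4 (log scale), evaluation budget 4000 (a full-design
fit converges in ~450–650 evaluations). By default the structural
constants are fixed (Fact, both allometric exponents, the 70-kg reference
weight), mirroring the original analysis; any parameter can be freed or
fixed by name. Standard errors come from the central-difference Hessian
of OFV/2 at the optimum on the log scale, so `RSE% ≈ 100·SE(ln θ)`; a
non-invertible Hessian falls back to the pseudo-inverse and flags the
fit.

The stepwise covariate search uses forward inclusion at ΔOFV ≤ −3.58
(the threshold used in the original analysis; note χ²₁(0.05) is 3.84 —
both are configurable) and backward elimination at 6.63 (χ²₁ at α=0.01,
the stated alpha; the exact backward criterion is not printed).
Covariates act multiplicatively on CL: binary as θ^x, positive
continuous as (x/median)^θ.

## Diagnostics

GOF records report DV, PRED (all effects zero), IPRED (at the EB modes)
and CWRES. CWRES is the FOCE linearization at the EB modes applied on
the **log** scale with the moment-matched `ln(1+ε)` residual; on data
simulated from the model it is standard-normal calibrated (mean within
±0.03, SD within 0.98–1.01 at n = 2,100). The concentration-scale
construction was implemented and measured first: at the model's
variability magnitudes it has a systematic mean bias of −0.08 to −0.10
(traced to the skewed log-normal geometry, not to the interaction term or
a missing second-order mean correction, both of which were tested), so it
was not retained. On exactly noise-free data the log-scale CWRES equals
the deterministic mean-correction offset (≈ σ/2), not zero; it vanishes
with σ.

The VPC simulates `n_sim` (default 500) replicates under the fitted
model with each subject's recorded regimen, weight, inhibitor status and
sampling times, bins observations by study day (24-h bins by default),
and reports observed 5th/50th/95th percentiles with the 90% simulation
band of each percentile. Empty bins are dropped with a warning. The
acceptance surface is the table (`VpcResult.to_frame`); PNG rendering is
optional.

## Dose individualization

`initial_rate` uses the steady-state identity trough = rate/CL with the
typical covariate-adjusted clearance: rate = target × CL_typ(WT, INH).
`adaptive_rate` estimates the subject's effects by MAP from observed
troughs, propagates the compartment amounts through the recorded dosing
history, and solves for the constant future rate whose predicted
concentration at the forecast horizon equals the target, by bisection
(the concentration is monotone in the rate; tolerance well below
1e−3 ng/ml). Defaults: target 8.5 ng/ml (window midpoint), horizon 24 h
(the next trough). κ for future occasions is 0 (prior mode) and the last
recorded inhibitor status carries forward. Per-kg rates are reported raw
and rounded to 0.01 µg/kg/h (pump granularity). Note the short-horizon
recommendation deliberately accounts for carried-over drug: for a
supratherapeutic steady-state patient it is *lower* than the steady-state
rate target × CL; at long horizons it converges to it (both are tested).

## Numerical choices and edge cases

- Predictions are floored at 1e−10 ng/ml inside variance terms; DV is
  floored at 1e−6 inside logs.
- The 2×2 matrix exponential uses the eigenvalue form; the discriminant
  is strictly positive for Fact > 0 (it equals k12² + 2k12(k10+k21) +
  (k10−k21)² with k10 = k21 under the Q/V2 tie).
- Inner finite-difference step 1e−4 (central); exact-Hessian step 1e−3;
  outer SE step 1e−3 on the log scale.
- Inner Newton line search halves up to 30 times per subject
  independently; a stalled subject keeps its best point.
- Non-positive-definite Hessians are eigenvalue-floored (quadrature
  metric) or identity-regularized with a log warning (Laplace block).
- Datasets must follow the daily-bag protocol (contiguous 24-h
  constant-rate bags from t = 0, at most one observation per bag) for
  population estimation; arbitrary overlapping segments are supported in
  the kinetics layer used for forecasting.

## Problem sizes used by the test suite and the acceptance script

The acceptance script runs the full study design (111 subjects ×
14 days, ~1,554 observations) twice: once with the standard free set
(θ_CL, θ_V1, θ_INH, ω_CL, ω_V1, π_CL, σ) and once with the clearance
allometric exponent additionally freed, on a fresh cohort. The test
suite exercises recovery on scaled-down replicates (typically 16–56
subjects) chosen so the whole suite completes at desk scale; the
covariate type-I-error calibration uses 200 small replicates with the
population parameters held at truth and only the candidate coefficient
free, the standard profiling shortcut for likelihood-ratio calibration.

## Known limitations

- The (π, σ) pair is weakly identified by trough-only daily sampling:
  the exact likelihood has a flat ridge trading inter-occasion
  variability against residual error, so single-cohort estimates of
  these two scatter more than the fixed effects (roughly ±10% at the
  full design). This is a property of the design, not the optimizer.
- Occasions without an observation are excluded from the integral
  (their κ is set to 0) although their κ in truth still influences later
  troughs through the carried state; under the default design every
  occasion has an observation, so this only matters with censoring.
- No Michaelis–Menten elimination, no time-varying clearance, no oral
  dosing, no covariance between η's, and no npde/prediction-corrected
  VPC.
- The titration rule and inhibitor-episode process are plausible
  stand-ins, not the clinical protocol.
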
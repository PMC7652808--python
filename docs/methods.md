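# Methods

## Structural model

State vector (8 states): propofol amounts in central and two peripheral
compartments (mg), the fentanyl analogues (µg), and one effect-site
concentration per drug. Central concentrations are amount/volume; effect
compartments are concentration states, `dCe/dt = ke0·(C − Ce)`, carry no
mass, and share one `ke0` across drugs. BIS is linked to the two effect-site
concentrations through the additive Emax model
`BIS = BIS0·(1 − Emax·U^γ/(1+U^γ))` with
`U = Ce_P/Ce50_P + Ce_F/Ce50_F + α·(Ce_P/Ce50_P)(Ce_F/Ce50_F)`; the final
estimates fix `Emax = γ = 1, α = 0`, so BIS reduces to `BIS0/(1+U)`. The
sigmoid is implemented as `U^γ/(1+U^γ)` (the standard response-surface
form); at the fixed `γ = 1` the placement of the exponent is immaterial.

Cardiac output is piecewise linear in surgery time: `CO(t) = CO0 + α_CO·t/60`
up to 300 min, constant afterwards (and held at that plateau through any
simulated washout — the model is explicitly not meant to extrapolate CO
recovery after surgery). Time is minutes everywhere; `α_CO` is stored in
(L/min)/h as reported and converted at evaluation. Before induction
(t < 0) CO is the baseline `CO0`. All six clearances (elimination and both
distribution clearances, both drugs) scale with `CO(t)/6.5`; volumes and
`ke0` never scale.

### Covariates and variability

The individual CO slope receives a proportional-linear covariate factor
`(1 + β_AGE/100·(age − 64))·(1 + β_STUDY/100·1{study=2})` applied before the
log-normal random effect (the two commute). An exponential form
(`exp(β/100·Δ)`) is available via `covariate_form="exponential"`; the linear
form is the default because both coefficients are reported in percent. The
factor is floored at 0.05 to prevent sign flips for extreme extrapolated
ages (configurable). Age is centred at 64 years, the cohort median.

Inter-individual variability is diagonal log-normal, `P_i = θ_P·exp(η_P)`;
reported %CVs convert as `ω² = log(1 + (CV/100)²)`. Residual error is
proportional for the two concentration streams (σ as a fraction) and
additive for BIS (BIS units) and CO (L/min).

## Simulation

`simulate_individual` integrates piecewise between dosing events with
LSODA (rtol 1e-8, atol 1e-10, dense output); events are hard breakpoints.
Boluses add to the central amount instantaneously; an ideal
plasma-concentration clamp (idealized target-controlled infusion) pins the
central concentration at its target by fixing the central state, and
`clamp_plasma_schedule` recovers the equivalent nonnegative input rate.
Observations at a dose time see the post-dose state.

Two independent integrators cross-validate each other:

* `matrix_exp_oracle` freezes CO at each step midpoint and propagates the
  resulting constant linear system exactly through 9×9 augmented matrix
  exponentials (second order in the step; exact when CO is constant). At a
  0.05-min step it agrees with the adaptive solution to better than 1e-6
  relative on all eight states.
* the estimation engine (below) exploits the model structure exactly.

### The warped-time propagation engine

Because CO multiplies every clearance, each drug's system matrix is
`A(t) = f(t)·B` with scalar `f = CO(t)/6.5` and constant `B`; such matrices
commute across time, so the homogeneous flow is exactly
`expm(B·Δτ)` on the warped clock `τ(t) = ∫ f`. `B` is diagonalized once per
parameter set and each grid step costs three scalar exponentials per drug.
Constant-rate inputs are added by 2-point Gauss–Legendre quadrature in real
time and the effect site by an exact exponential step on a
linear-in-time central concentration; both are second order in the grid
refinement (default 1 min, with a geometric burst of extra nodes after each
dosing discontinuity to resolve the fast central transient, time constant
≈ 0.5 min for propofol). Measured against the adaptive solver the engine is
accurate to ~1e-3 relative on concentrations and ~0.05 BIS units at the
default refinement — far below the residual scales (38.6 % CV, 8.4 BIS
units). The estimation experiments use a 2-min refinement; the associated
~1 % prediction bias is negligible against the ±30 % recovery tolerance.
The kernels are numba-compiled.

## Synthetic trials

The generator emulates a pooled two-arm design (default 11 + 11 subjects):
ages uniform on 51–80 y, weights on 57.5–105 kg; fentanyl 1.5 µg/kg bolus at
t = −5 min; propofol infusion from t = 0 titrated every 10 min by ±20 %
proportional steps whenever the noise-free model BIS leaves the 40–60 band;
fentanyl top-ups (uniform 2–3 µg/kg) at Poisson surgical-stimulus times
(mean 2/h), thinned by adequacy of anesthesia (no top-up when the noise-free
BIS is already below the band floor — giving more opioid to an already-deep
patient would be clinically implausible and makes the band unattainable for
fentanyl-sensitive subjects). The initial infusion rate of 4.0 mg/min is
derived from the final typical estimates: targeting mid-band BIS 50 gives
`U = 0.77`, of which the loading fentanyl contributes ≈ 0.17, so the
propofol plasma target is ≈ 1.35 mg/L, and at baseline CO the required rate
is `1.35·(Cl+Q1+Q2)·CO0/6.5 ≈ 4 mg/min`. Surgery durations are uniform on
150–300 min (unreported in the source study; typical for open aortic
repair).

Arterial PK samples follow the study schedule (1, 3, 5, 10, 15, 30 min,
then every 30 min until cessation, then a study-specific washout series
extending to +240 min for arm 2); BIS and CO are recorded every 5 min (a
tractable stand-in for near-continuous monitoring) from induction to one
hour past cessation. Residual noise follows the residual model; BIS is
clipped to [0, 100]; concentrations under the assay limits (propofol
0.01 mg/L, fentanyl 0.05 ng/mL) are flagged BLQ and retained. Everything is
reproducible from (designs, parameters, seed).

What the generator does **not** emulate: assay error structure beyond the
proportional model, sampling-time deviations, measured-CO artifacts of
pulse-contour monitors, hemodynamic covariates other than CO, or the actual
clinicians' titration policy. Passing recovery/coverage tests therefore
demonstrates internal consistency of the estimator with the assumed model,
not robustness to the misspecifications a real trial would add.

## Estimation

The per-subject marginal likelihood uses a Laplace expansion about the
conditional mode of the random effects with the Gauss–Newton curvature
`J'WJ + Ω⁻¹` evaluated at conditional predictions, so residual variances
track the conditional predictions ("interaction"). The OFV is the full
−2 log-likelihood including 2π constants; nested-model differences are
χ²-referenced. BLQ-flagged records are excluded by default.

Numerical choices:

* Inner problem: damped Gauss–Newton (Levenberg–Marquardt) on η with
  finite-difference Jacobians (step 1e-4), cold-started every evaluation
  from a fixed grid (0 and ±0.5 on each axis when multistart is enabled) so
  the outer objective is a deterministic pure function of the population
  parameters. Gradient tolerance 0.02 (∞-norm), which reproduces the OFV to
  ~5e-3.
* Outer problem: L-BFGS-B on transformed parameters (log for positive
  parameters and variances, percent/100 for covariate coefficients) within
  generous box bounds. Gradients are finite differences evaluated with the
  conditional modes frozen at their current values — by the envelope
  property the modes' own displacement enters only at second order — which
  makes a gradient cost ~14 model evaluations per subject instead of a full
  inner re-optimization per parameter.
* Degenerate corners of parameter space (failed linear algebra,
  non-positive proportional predictions) return a large finite objective so
  line searches back off gracefully.
* Standard errors (optional) come from the inverse of a central-difference
  Hessian at the optimum, delta-method-transformed to the natural scale;
  η-shrinkage is `100·(1 − SD(EBE)/ω)`.
* CO-effect variants: `model` (CO predicted by the individual's profile),
  `observed` (last-observation-carried-forward measured CO drives the
  clearance scaling), `none` (no CO scaling). The CO observation stream is
  always fitted with the model CO profile.

The bootstrap resamples subjects with replacement (same n), refits each
resample, and summarizes parameter distributions as the median with the
5th–95th percentile interval; failed fits are excluded and counted, and more
than 50 % failures is an error.

## Diagnostics

pcVPC: replicate datasets are simulated under the fitted model with the
original designs and covariates; observed and simulated records are
prediction-corrected by the bin-median population prediction (ratio form for
CP/CF/CO, additive shift for the bounded BIS scale), then the observed
10th/50th/90th percentiles per equal-count time bin (default 10 bins, bins
under 5 observations merged) are compared with the 2.5–97.5 % envelope of
the same percentiles across replicates. CWRES linearizes the model about
each subject's conditional mode and whitens residuals with the Cholesky
factor of `JΩJ' + Σ`.

## Scaled-down validation experiments

The packaged experiments are sized to run on one CPU in minutes; sizes are
the package's own choices and are what the test suite runs:

* Parameter recovery: one 22-subject two-arm trial (seed 42) at the final
  estimates; the 18 fixed effects with reported RSE < 50 % are perturbed by
  ×U(0.8, 1.25) and re-estimated jointly; `ke0` and `Ce50_F` (reported
  RSE > 50 %) and all variance/residual parameters are fixed at their
  generating values. Recovery criterion: every estimated fixed effect
  within ±30 % of truth.
* Covariate power: 20 trials; the age effect on the CO slope is added to a
  reduced model (both models estimating the slope, everything else fixed at
  truth) and the LRT at ΔOFV > 3.84 is counted.
* pcVPC calibration: 200 replicates, 8 bins, on a self-simulated trial.
* Bootstrap coverage: 8 trials of 8 subjects with IIV restricted to
  (Cl_P, CO0, α_CO), 20 resamples each, two estimated parameters; 90 %
  intervals should cover the generating values ≈ 90 % of the time (wide
  acceptance band, the Monte-Carlo error at 16 indicators is large).

## Decrement-time analysis

`csdt` clamps both plasma concentrations (not effect sites) at the targets
for the maintenance period — with `ke0 = 0.105 min⁻¹` the effect sites reach
> 99 % of target well before 200 min, so the distinction is immaterial — with
the CO clock starting at clamp onset, then stops all inputs and locates by
bisection (0.01-min resolution on dense solver output) the first time the
virtual effect-site concentration `U = Ce_P/Ce50_P + Ce_F/Ce50_F` falls to
`(1 − d)·U(maintenance end)`. Decrements not reached within the horizon
(default 600 min) are reported as censored, not raised.

Two decrement conventions are implemented. The plain fractional decrement
on U (`definition="u"`) and the published decrement→BIS mapping
(`definition="bis"`, the default), under which a "d %" decrement denotes
reaching the BIS value `BIS0/(1 + (1−d−0.1)·U_maint)` — exactly one 10 %
step deeper on the additive Emax curve. The mapping convention reproduces
seven of the eight published scenario times to within 1–7 %, while the
plain-U convention reproduces none of them; the remaining scenario
(Study 1, age 50, 80 % decrement) disagrees by ~+49 % under every
parameterization variant we examined and appears internally inconsistent
with the neighbouring published values (see the known-limitations note
below).

## Known limitations

* CO is assumed constant after 300 min and through washout; decrement times
  for long horizons inherit that crude assumption.
* The FOCE approximation uses Gauss–Newton curvature; for large residuals
  it deviates from the exact Laplace value (tested at ~1 % of the OFV on a
  scalar model with a 0.5-SD residual).
* The engine's input quadrature is second order; extremely rapid rate
  switching (sub-minute) should use the adaptive solver path.
* One published decrement-time scenario (Study 1, age 50, 80 %) is not
  reproduced by this implementation under any examined reading of the
  model; the other seven scenarios match closely.
* Bootstrap intervals at 8 subjects undercover slightly, as expected for
  subject-level resampling at small n.
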
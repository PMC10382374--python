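# Methods

This note documents the model, the choices that were genuinely open when
building it, and what the package's tests do and do not demonstrate.

## Scope and model structure

One simulated patient is a coupled system of three linear sub-models:

- a 1-D multilayer diffusion problem (patch → stratum corneum → viable
  epidermis → equivalent dermis) per application site,
- a five-compartment pharmacokinetic balance fed by the summed bottom
  flux of all active sites,
- two effect compartments mapping plasma concentration to VAS pain and
  minute ventilation through decreasing sigmoid-Emax curves.

The physical problem is two-dimensional (a patch on a skin block), but
the lateral boundaries carry no flux and all initial and boundary data
are laterally uniform, so the exact solution is one-dimensional; the
package solves the 1-D problem directly.

Between patch events the full coupled system is linear and
time-invariant, which the integrator exploits (below). Pain feedback
enters only at discrete checkpoints, so the closed loop is a sequence of
linear initial-value problems separated by state transformations (patch
removal and application).

## Skin transport

Diffusion is solved in the drug-potential form ψ = c/K. The capacity K
per layer (patch 1.0; all skin layers 3.4) realizes the interface
partition coefficients K_patch/K_epidermis = 1/3.4 = 0.29 and
K_epidermis/K_dermis = 1; only the ratios are physically meaningful.
A single epidermis diffusivity (3.02e-14 m²/s) serves both the stratum
corneum and the viable epidermis, which remain separate layers for
thickness bookkeeping; the patch and dermis use 6.91e-16 and
3.84e-11 m²/s. The equivalent-dermis thickness is the reduced depth at
which pure diffusion reproduces capillary drug uptake, so no advection
term is modelled.

Discretization is a conservative finite-volume scheme: cell balance
d(Kψ)/dt per cell, face fluxes from series (harmonic) composition of the
two half-cell resistances h/(2DK). This composition enforces flux
continuity and the partition jump at layer interfaces without any
special-casing. The top face is no-flux; the bottom face imposes the
Dirichlet potential ψ = c_p/K_dermis (concentration continuity with
plasma, no extra blood partition coefficient). Cell widths follow a
smooth symmetric stretching s(ξ) = ξ − β sin(2πξ)/(2π) within each layer
(β = 1 − 1/refinement, default refinement 2.0), concentrating cells at
interfaces. Because the stretching is independent of the cell count,
doubling the count refines the same grid family, and the Richardson
study on the bottom-flux functional observes clean second-order
convergence. The default resolution (28/20/20/32 cells per layer, 100
total) keeps the bottom-flux discretization error below 0.1% of the
Richardson extrapolate; sealed-outlet mass balance closes to solver
tolerance (≪ 0.1% of the 12.6 mg load over 72 h).

## Pharmacokinetics

Compartments: central (blood + lungs), rapid (brain, heart, skin,
kidneys), slow (muscle, fat, carcass), gastrointestinal (gut, spleen,
pancreas), hepatic. Rate constants are never stored: the parameter set
keeps volumes V and flows Q, and each balance equation derives its
coefficient as Q divided by the volume of the compartment that equation
describes, so the same physical flow appears with different rate
constants in different equations.

Two structural choices deserve record:

- **Unbound-fraction placement.** The unbound fraction f_u = 0.20 gates
  every flux leaving the central compartment, and the receiving
  compartment collects exactly the gated flux. The alternative — gating
  only the central-side bookkeeping while tissues collect the full flux —
  creates drug amount in every central→tissue transfer; at tissue
  quasi-equilibrium the return flux then exceeds the central loss by
  (1 − f_u)·ΣQ, giving the system a positive eigenvalue and exponential
  blow-up within minutes. That variant is retained behind
  `literal_fu_central_only` for inspection, but the conservative
  placement is the only dynamically viable reading and is the default.
  With elimination off and f_u = 1 the total amount is conserved to
  integrator tolerance (tested).
- **Renal term sign.** Renal clearance acts as elimination from plasma.
  A `literal_eq4_sign` flag flips it to a source term for inspection;
  it is off by default for the obvious physical reason.

The reference volume/flow tables per gender (for a 70-kg reference
patient, scaled linearly by weight/70) are configuration data, not
printed constants. Volumes are lumped-organ physiological values. The
flows are *effective* inter-compartment clearances: once f_u gates the
central outflow, anatomical perfusion rates are not identifiable in this
lumped structure, so the flows and the hepatic/renal clearances were
calibrated once so that simulated conventional therapy lands inside the
study's reported outcome ranges (maximum plasma concentration
1.3–3.2 ng/ml, minimum VAS 0–5, minimum ventilation 2.5–10 L/min across
the population). With the shipped defaults the simulated population
spans 1.34–3.22 ng/ml, 0.5–4.9 VAS and 2.9–9.0 L/min. Comparative
population percentages (e.g. the exact percent reduction in mean pain)
remain sensitive to this table and are therefore asserted only
directionally.

## Pharmacodynamics

Each endpoint is a first-order effect-compartment lag (k_e = 2e-3 1/s
for pain, 7e-4 1/s for ventilation — the pain site equilibrates ~2.9×
faster) followed by a decreasing sigmoid E = E0 − Emax·Hill(c_e). Pain:
E0 = Emax = 8 VAS units, γ = 2.71, EC50 = (1.96 − 0.01148·age) ng/ml per
patient. Ventilation: E0 = 20 L/min, Emax = 0.91·E0, EC50 = 1.14 ng/ml,
γ = 2.69. At c_e = 0 the Hill term is exactly zero (no 0^γ ambiguity),
so baselines are exact; at c_e = EC50 each effect is exactly halfway to
its maximum.

## Patient parameterization

Covariate formulas (gender coded 1 = male, 0 = female):

- SC thickness [µm]: (0.125·age + 11.80·(gender + (1−gender)·1.40))·exp(θ).
  Implemented literally; the implied population mean is ≈ 21.3 µm,
  whereas the study tabulates 18.0 µm for the same expression, so the
  literal formula is kept and an optional global `sc_calibration_factor`
  (default 1.0 = off) exposes the discrepancy rather than hiding it.
- Viable epidermis [µm]: base·(gender + (1−gender)/1.11)·exp(θ). The
  base value is not printed; it is calibrated so the reference
  population mean equals 29.7 µm (shipped value 31.085 µm).
- Equivalent dermis: a BMI-linear branch per gender (0.0369·BMI + 0.9531
  male, 0.0325·BMI + 0.8915 female — millimetres) times a calibrated
  age-scaling ratio (0.13402) so the population mean equals 242.6 µm,
  times exp(θ). The BMI expression is only accepted for BMI in [15, 45].
- PK volumes, flows and clearances: per-gender reference × weight/70 ×
  exp(θ), one independent θ per entry.
- Pain EC50: the age-linear expression × exp(θ).

Every θ ~ N(0, 0.1) is drawn independently per parameter per patient and
recorded in the twin, so a twin is reproducible from (patient, seed) and
any parameter's ratio to its deterministic value equals exp(θ) exactly.
sd 0.1 puts ~95% of multipliers within ±20%. Calibration of the two
skin scalars is deterministic given a reference population (expectation
over exp(θ) taken analytically), hence idempotent.

## Synthetic sample cohort

The 20-patient cohort that anchors the population model exists in the
literature only as summary statistics. The generator reproduces those
summaries *exactly* rather than approximately: gender is fixed at 10/10;
residuals orthogonal to the gender vector are rotated (Cholesky of the
residual correlation matrix) to hit the three printed correlations
(gender–height 0.87, gender–weight 0.43, weight–height 0.38; unprinted
pairs set to 0) and affinely rescaled to the printed means and SDs (age
56.75 ± 9.82 y, weight 72.8 ± 14.8 kg, height 1.70 ± 0.12 m). A
whole-cohort rejection loop enforces the printed age range [40, 68] and
BMI ∈ [15, 45]. One non-obvious consequence: a mean of 56.75 and SD of
9.82 strictly inside [40, 68] forces an edge-heavy (U-shaped) age
distribution — the moment-implied Beta shape parameters are both < 1 —
so the age residual is drawn from that Beta shape, which is also the
only qualitative statement about the real cohort's age histogram those
three numbers permit.

What the generator does **not** emulate: the real patients' tumour
sites, treatment histories, any non-Gaussian structure in weight/height,
and any correlation the summaries do not pin down. Tests passing against
this cohort show the pipeline reproduces the published summary
statistics, not that it recovers the unpublished individuals.

## Virtual population

Gibbs sampler over gender ~ Bernoulli(p) (Beta(1,1) prior) and
per-gender (age, weight, height) ~ MVN with a conjugate
normal–inverse-Wishart prior centred on the per-gender sample moments
(prior strength 1 pseudo-observation, ν₀ = d + 2 so E[Σ] equals the
sample covariance). Default 20 000 burn-in sweeps, then one
posterior-predictive patient per kept sweep (3000 kept = the
population); out-of-bounds draws are rejected and redrawn. Modelling the
continuous block per gender reproduces the gender–height gap that a
single dichotomised Gaussian would blur. The population reproduces the
sample means and the correlation structure (population-vs-sample ρ
within 0.15 for every pair, tested).

Published population SDs are roughly half the sample SDs; predictive
draws cannot shrink below the likelihood spread, so the mechanism behind
that shrinkage is not reproducible from the printed information. The
sampler exposes `draw="parameter_mean"` (emit the posterior mean instead
of a predictive draw), which produces such shrinkage; the default
remains predictive, and no mean-level result depends on the choice.

## Therapy simulation and controller

The conventional policy applies one patch at t = 0 and replaces it only
at multiples of 72 h (within a 72-h horizon: exactly one patch). The
twin-assisted policy evaluates the simulated VAS at every checkpoint
(default 8 h; supported set 2, 4, 6, 8, 12, 24, 36, 72 h) and replaces
the patch iff VAS is *strictly above* the target 3 at that instant (not
a running average). The first check at t = Δt implements the intended
lockout against over-frequent changes. "Time without pain" counts VAS
*strictly below* 3, with crossing times located by linear interpolation
of the hourly series; a value exactly at 3 neither counts as pain-free
nor triggers replacement. Both the total and the longest contiguous
pain-free duration are reported.

A replacement removes the old patch and applies a fresh 12.6 mg patch of
the same 31.5 cm² area at a new drug-free site. The old site's skin
depot keeps releasing by default (`residual_depot: true`), since the
drug already in the skin does not vanish when the patch moves; setting
it false retires the old site instead, and both modes are exercised in
tests. The plasma input is the sum of bottom fluxes over all active
sites.

## Numerics

- Monolithic method-of-lines integration of all active sites + PK +
  effect states with BDF and an analytic Jacobian. The system matrix is
  assembled by probing the composed right-hand side with unit vectors —
  exact for a linear system and automatically consistent with the public
  per-module operators (asserted in a test).
- Each inter-event segment is integrated on a segment-local clock
  starting at 0: the system is autonomous, and restarting the clock
  keeps the stiff solver's initial-step selection clear of the
  eps·|t| step-size floor immediately after a patch-event discontinuity.
- Tolerances: rtol 1e-6; atol is per-block (1e-9 ng/ml for
  concentrations, the equivalent 1e-3 ng/m³ for potentials, 1e-9 of the
  patch load for the cumulative-outflux audit states). Maximum internal
  step 6 h; output every 1 h. Tightening rtol 10× moves hourly plasma
  concentration by far less than 0.1% (tested).
- Events fall on the hourly grid by construction of the supported
  checkpoint set; event instants are exact integration breakpoints, and
  no interpolation is performed across an event.
- Degenerate inputs: zero-thickness layers, fewer than 4 cells per
  layer, non-PSD correlation targets, single-gender samples, empty
  heavy-user subgroups and missing reference-table entries all fail (or
  report missing values) explicitly rather than silently.

## Problem sizes used by the test suite

Population statistics are verified at the full study size (20 000
burn-in, 3000 kept; a few seconds). The two-arm comparative properties
are verified on a 200-member population — large enough that every
directional claim (higher median pain-free time, smaller IQR, lower pain
mean and SD, higher pain-free fraction, patch-count–weight correlation,
heavier and more male heavy-user subgroup) is stable across seeds, and
small enough to run in about a minute. Unit tests use coarser grids
where spatial accuracy is immaterial to the logic under test.

## Known limitations

- No norfentanyl metabolite kinetics, no CO₂ feedback on ventilation,
  and no liver-enzyme or kidney-function covariates; the four covariates
  are age, gender, weight, height.
- The controller reacts to pain only; hypoventilation and plasma
  toxicity are reported as outcome flags (2 ng/ml default threshold,
  3 ng/ml configurable) but do not veto a replacement.
- Absolute comparative percentages depend on the effective-clearance
  reference table (see Pharmacokinetics) and should be read as
  model-conditional; the directional conclusions are robust to it.
- Patch size is fixed; dose titration by area is out of scope.
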
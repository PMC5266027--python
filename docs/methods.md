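# Methods

This note records the modelling decisions behind `bolusim`: what is being
simulated, which constants were free choices, and what the shipped tests do
and do not demonstrate.

## Model structure

The simulator tracks iodine mass through a fixed circulation topology of 35
compartments: 26 purely vascular segments and 9 exchange organs (lung,
brain, coronary, upper extremities, liver, gastrointestinal tract, spleen,
kidneys, lower body).  Each vascular segment is one well-mixed state; each
organ is two (vascular + extracellular, coupled by a permeability–surface
product *PS*), giving 44 coupled linear ODEs when the venous loop is
closed.  The system matrix is constant for a given patient, and the bolus
enters as a rectangular mass-rate forcing at the antecubital vein.

Two deliberate simplifications:

* **Single-pass default.**  Recirculation of contrast through the venous
  return is omitted by default: the four venous-return edges
  (jugular→SVC, IVC→right atrium, coronary→right atrium, arm→antecubital)
  are redirected into an absorbing sink, and the compartments they fed
  receive contrast-free make-up flow of the same magnitude.  This isolates
  the first pass — the part of the curve that determines ME and TTP over a
  50 s scan — at the cost of slightly underestimating the late tail.
  `recirculation=True` closes the loop for sensitivity studies.
* **Transport delays as compartment chains.**  Pure delays (e.g. the
  peripheral venous path from the injection site) are realised as short
  serial chains of small vascular compartments rather than
  delay-differential terms, keeping the system a plain ODE.

The brain's *PS* is zero in the default table: iodinated contrast does not
cross an intact blood–brain barrier on first-pass time scales, so the
cerebral tap is purely intravascular.  Other organ *PS* values (0.2–2.5
mL/s) are order-of-magnitude reference choices that shape the tail, not
fitted quantities.

## Patient scaling

* Total blood volume: the sex-specific anthropometric regression
  `BV[L] = a·H[m]³ + b·W[kg] + c` with Nadler's coefficients
  (male: 0.3669/0.03219/0.6041; female: 0.3561/0.03308/0.1833).  For the
  reference adult (male, 170 cm, 75 kg) this gives 4 820.9 mL.
* Cardiac output: `CO = CO_ref · (W / 70 kg)^0.75` with `CO_ref` =
  6 500 mL/min, i.e. 114.1 mL/s for the 75 kg reference adult.  No sex
  adjustment is applied; sex enters through blood volume only.
* Regional flows and blood volumes are fixed fractions of CO and BV taken
  from reference-man physiology (brain 12 %, kidneys 19 %, liver 25 % of
  CO, etc.).  The fractions are stored — and checked to sum to one — in
  `src/bolusim/data/default_config.yaml`, the single audit point for every
  physiological assumption.
* Extracellular organ volumes scale linearly with body weight (mL/kg
  table values).

These formulas reproduce the qualitative behaviour that matters clinically:
heavier patients dilute the bolus (ME falls monotonically with weight at
fixed height and sex) and transit the faster circulation slightly sooner.

## Numerics

The two constant-forcing phases (during and after injection) are integrated
separately with an adaptive high-order Runge–Kutta method (DOP853,
rtol 1e-8 / atol 1e-10) and stitched; dense output is resampled onto a
0.1 s grid, so the output step never affects the dynamics.  Because every
flow leaving a compartment arrives somewhere (sink included), the matrix
columns sum to zero exactly and total mass tracks the cumulative injected
mass to machine precision; the test suite enforces 1e-6 relative as the
contract.  Solver undershoot below zero (bounded by the absolute tolerance)
is clipped in the reported curves.  The integrator is cross-checked against
the closed-form two-tank washout solution and against a piecewise-exact
matrix-exponential solution of the full 45-state system.

## Enhancement calibration

CT enhancement is linear in iodine concentration; the shipped coefficients
are 49 HU/(mg I/mL) at 80 kV and 26 at 120 kV — standard literature
sensitivities, larger at 80 kV because it sits nearer the iodine k-edge.
With them the reference adult peaks at 375.9 HU enhancement over the 50 HU
background, in the 350–500 HU range typical of arterial first-pass
measurements at this protocol.  `calibrate_from_pairs` fits the one free
scale factor from measured (concentration, HU) pairs when a
scanner-specific value is available.

## Metric conventions

* TTP is measured from injection start; a `ttp_origin: scan` config flag
  shifts by the 5 s scan delay for scan-clock conventions.
* Peak ties break to the earliest sample; no sub-sample interpolation by
  default (clinical TTPs are reported at integer seconds), with parabolic
  refinement behind a flag.
* Auto-baseline is the mean of the first 5 s of samples (pre-arrival under
  the standard delay); an explicit baseline always overrides.
* MTT is strictly the venous-minus-arterial peak-time difference, not a
  deconvolution transit time.

## Synthetic cohorts

The generator emulates the structure of a two-group clinical validation:
controls (default 19 M / 25 F) and infarct patients (46 M / 11 F), with
per-sex anthropometry male 170 ± 6 cm / 70 ± 10 kg, female 160 ± 6 cm /
60 ± 10 kg — plausible adult values, configurable, and not claimed to match
any particular cohort's unpublished demographics.

A patient's "measured" curve is their simulated curve under a measurement
model: amplitude scaled by an ME attenuation factor (1 for controls,
default 0.8 for infarct), time-shifted by a Gaussian TTP jitter
(sd 2 s), and perturbed by a single Gaussian amplitude draw (sd 30 HU)
applied along the unit-peak bolus shape.  The shape-weighted single draw is
deliberate: it makes the extracted ME exactly
`factor × ME_sim + N(0, 30 HU)`, so the stated noise level is the noise
level of the *metric*.  Independent per-sample noise on a dense grid would
instead inflate every extracted peak by roughly three standard deviations
(the maximum of hundreds of draws) and break that correspondence.  Infarct
cohorts additionally generate the measured curve from a cerebral-flow-
reduced circulation (carotid subtree scaled, deficit rerouted through the
lower body with flow conservation intact), which delays the measured TTP,
while the paired "simulated" prediction always uses healthy physiology.

What this does **not** emulate: real ROI placement variability, partial
volume and beam-hardening effects, patient motion, or any disease
physiology beyond a proximal flow reduction — so green validation tests
show the pipeline's statistical machinery is calibrated, not that the model
matches real patients.

Monte-Carlo calibration replicates redraw the metric-level noise around the
once-simulated cohort (exactly equivalent to redrawing the curve-level
perturbation, by the construction above): 2000 null replicates of the n=44
cohort put the paired t-test's type-I error at ~5 %, and 200 replicates of
the n=57 cohort detect a 20 % ME attenuation with power ≈ 1.

## Problem sizes and determinism

Default runs use a 90 s horizon at 0.1 s output resolution (901 samples,
45 states); a full 44-patient cohort simulates in about two seconds on one
core.  All randomness flows from a single integer seed through
`numpy.random.default_rng`; the validate workflow is byte-identical across
runs at a fixed seed.

## Known limitations

* The reconstructed topology is one plausible realisation of a Bae-style
  whole-body model; the exact equation set of any particular published
  implementation (chamber mixing details, delay placements) is not claimed
  to be replicated, only the state dimension and architecture.
* No venous cerebral (sagittal-sinus) tap ships in the default output, so
  per-patient simulated MTT is unavailable; MTT comparisons operate on
  measured curves only.
* No renal elimination over the simulated horizon (negligible within
  60–90 s), no osmolality/viscosity nonlinearity, no injection-volume
  perturbation of blood flow.
* The HU calibration and organ *PS* values are literature-scale constants,
  not fitted to scanner or patient data; absolute HU predictions carry the
  corresponding systematic uncertainty.
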
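# Methods

`emg2torque` computes ankle joint torque from surface-EMG (sEMG) envelopes
and joint angles, and calibrates the model's physiological parameters
against measured torque. This note documents the model, its numerical
treatment, the synthetic data that stands in for human recordings, and the
design decisions taken where the design was genuinely open.

## Model

### Activation dynamics

The MVC-normalized envelope `e(t)` of each muscle is converted to neural
activation `u(t)` by an electromechanical delay `de` (default 40 ms,
realized as an integer sample shift, round-half-up) followed by the
second-order recursion

    u(t) = α·e(t − d) − β1·u(t−1) − β2·u(t−2)

with defaults α = 0.9486, β1 = −0.052, β2 = 0.000627. The characteristic
roots of `z² + β1 z + β2` are real and below 0.06 in magnitude, so the
filter is a stable, essentially unit-DC-gain pass-through
(α/(1+β1+β2) ≈ 0.99997); it is implemented as an IIR filter
(`scipy.signal.lfilter`) with zero initial conditions. Muscle activation is
the monotone nonlinear shaping

    a(t) = (e^{A·u} − 1)/(e^A − 1),   A ∈ (−3, 0), default −1.5.

`u` is clipped to [0, 1] before shaping (clipping is logged; with the
default coefficients the raw recursion can overshoot the unit interval by
at most ~6·10⁻⁴, so clipping is defensive). The sampling rate is a free
parameter (default 1000 Hz); the delay must resolve to fewer samples than
the series length.

### Muscle–tendon unit

Each muscle is a Hill-type unit: contractile element and parallel elastic
element (the fiber, length `lm`, pennation `φ`) in series with a tendon
(length `lt = lmt − lm·cos φ`). Forces:

* active: `FAm = fA(l)·fv(v)·a·F0m`, with `fA(l) = q0 + q1·l + q2·l²` on
  l ∈ [0.5, 1.5] and 0 outside (q = −2.06, 6.16, −3.13; fA(1) = 0.97);
* passive: `FPm = e^{10l−15}·F0m`;
* tendon: slack below `lst`, toe region `1480.3·ε²·F0m` for
  0 < ε < 0.0127, linear `(37.5·ε − 0.24)·F0m` beyond (the two branches
  disagree by 0.0025·F0m at the knee — an accepted property of the printed
  constants, asserted in the tests);
* force–velocity: `fv = 0.3(v+1)/(0.3−v)` for shortening (v = vm/v0m < 0),
  `fv = (2.34v+0.039)/(1.3v+0.039)` for lengthening; value 1 at v = 0,
  zero at v = −1, eccentric asymptote 2.34/1.3 = 1.8.

The normalized length `l` uses the activation-scaled optimal length
`l0m(t) = l0m·(λ(1−a)+1)`, λ = 0.15 (a config switch restores plain `l0m`
normalization). Pennation follows the constant-height model
`φ = asin(l0m·sin φ0 / lm)` with the plain optimal length, clamped to π/2
when the fiber falls below the fixed height.

### Fiber-state solution and integration

At each step the tendon force implied by `lt` must equal the projected
fiber force; solving for the force–velocity value gives

    fv = (Ft − fP(l)·F0m·cos φ) / (fA(l)·a·F0m·cos φ),

and the closed-form inverse of the force–velocity curve (each branch is a
Möbius function) yields `vm`. `dlm/dt = vm` is integrated with classic
4th-order Runge–Kutta at the sampling interval; activation and `lmt` are
linearly interpolated at half steps. The initial fiber length defaults to
`l0m` (the resulting brief start-up transient — the fiber settling onto its
equilibrium — is a documented property of this initialization; `lm0` can be
supplied per muscle).

Degenerate cases are handled by clamping, never by exceptions
mid-integration:

* activation is floored at `a_min = 0.01` inside the fiber dynamics. This
  is the standard activation floor of EMG-driven models; it also bounds the
  stiffness of the contraction dynamics (the relaxation rate of the fiber
  toward its force balance scales like 1/a), which keeps fixed-step RK4 at
  1 kHz in its stability region at rest. At lower sampling rates the
  integrator is accurate for the smooth trials used here but the activation
  floor should be revisited;
* the denominator of fv is floored at 10⁻⁶·F0m·cos φ;
* fv is clamped into [0, fv(+1) = 1.7767] before inversion, confining
  fiber velocities to [−v0m, +v0m]. Clamp events are counted and reported
  per run as a numerical-health signal.

Integration aborts (with the muscle and step named) if `lm` leaves
(0.25, 2.5)·l0m; during calibration such aborts become a large finite
penalty (10¹²).

The inner loop is compiled with numba; a pure-Python reference integrator
(`engine="python"`) implements the same model through the public curve
functions, and the tests assert the two engines agree and that RK4 agrees
with a 100×-finer explicit-Euler oracle.

### Geometry and torque

Musculotendon length per (muscle, DOF) is a cubic in the joint angle,
`lmt(θ) = μ0 + μ1θ + μ2θ² + μ3θ³`, and the moment arm is its exact
derivative `r(θ) = μ1 + 2μ2θ + 3μ3θ²`. Joint torque is `Σ r_i(θ)·F_i`.
The moment arm is defined as +∂lmt/∂θ (no minus sign); all direction signs
are absorbed into the per-muscle coefficients, with positive torque meaning
dorsiflexion / inversion / internal rotation and θ = 0 the neutral seated
posture (shank and sole at 90°).

No published coefficient values exist for this bench, so the package ships
default polynomials (clearly labelled package defaults, overridable via
config). Their intercepts are `μ0 = lst + l0m·cos φ0`, i.e. the tendon is
exactly slack at neutral with the fiber at optimal length. Their moment
arms at neutral (sagittal: ta +0.020 m, sol −0.018 m, gm −0.015 m,
gl −0.014 m; smaller arms for the frontal and transverse DOFs) were chosen
under the constraint |r·ROM| ≲ 0.3·l0m: with the anatomical optimal fiber
lengths of 0.03–0.06 m, larger arms (e.g. the often-quoted 4–5 cm for the
sagittal plane) would drive the fibers out of the active force–length
support over a 30–45° sweep and let passive force dominate, which the
short-fiber parameter set cannot support. Each DOF has its own polynomial
set. The bench's load-cell conversion is `T_i = F_i·l_i` with arms
(0.050, 0.200, 0.040) m.

## Calibration

Sixteen parameters — F0m, l0m, lst, φ0 for each of the four muscles — are
optimized to minimize the summed squared torque mismatch over the
calibration trials. Bounds are ±50% of the initial anatomical values for
F0m, l0m, φ0 and ±15% for lst; v0m is held at 10·l0m(initial) per second
and not recomputed from candidate l0m (contraction speed has little effect
on the result and is not calibrated).

The genetic algorithm uses binary coding (default 12 bits per parameter,
linear quantization over the bounds, so decoded candidates are always
feasible; resolution e.g. ~0.3 N for a 1270 N force range, far below the
noise sensitivity of the objective), roulette-wheel selection, single-point
crossover with probability 0.6, mutation with probability 0.1, and elitist
carry-over of the single best individual, which makes the best-so-far trace
nonincreasing. The initial population contains one individual encoding the
initial anatomical values (the benchmark the search is defined around) and
otherwise random codewords.

Two details matter for convergence within a small evaluation budget and
were chosen after comparing alternatives on held-out scenarios. First, the
roulette weights are derived from population rank (0.85^rank): weights
computed directly from a large-valued objective, e.g. 1/(1+objective),
make selection nearly uniform and the search stalls. Second, the mutation
probability is drawn per parameter block (flipping one random bit of that
parameter; expected ~1.6 flips per individual) rather than once per
individual — with per-individual mutation only a handful of bits change
per generation and the population converges prematurely; per-individual
and per-bit modes remain available via ``GAConfig``. Activations,
musculotendon lengths and moment arms do not depend on the calibrated
parameters and are precomputed once per trial, so each objective
evaluation only reruns the fiber integration.

Study-scale settings are population 100 / 150 generations. Tests and the
acceptance script use the reduced scale population 40 / 60 generations,
which keeps a full calibration around one to two minutes on one CPU at the
default trial sizes.

## Synthetic data

The generator emulates the seated ankle-bench protocol: per movement, the
joint angle sweeps 0 → ROM → 0 as a half-sine over the trial (defaults:
dorsiflexion +30°, plantarflexion −45°, inversion +15°, internal rotation
+35°, external rotation −25°; 5 s at 1000 Hz). EMG envelopes are Gaussian
bells over a 0.02 resting baseline with movement-specific agonist
amplitudes that mirror the observed contribution pattern (tibialis
anterior dominates dorsiflexion; the triceps surae — strong muscles at low
normalized effort — drive plantarflexion; during inversion the triceps act
early and tibialis anterior late; soleus is nearly silent in internal
rotation, the medial gastrocnemius in external rotation). Effort levels
were set once so that peak torques land at ~5–20 N·m, the scale a damped
rehabilitation bench produces.

Noise: envelope noise is band-limited (white Gaussian smoothed to ~50 ms
correlation, rescaled to SD 0.02, added, then clipped to [0, 1]) because
envelope fluctuations in rectified-and-filtered EMG are low-frequency;
torque noise is white with SD 5% of the trial's peak torque. The stored
torque is the forward model run on the stored noisy envelopes plus the
torque noise, so every trial is exactly self-consistent with its own
inputs: at the true parameters the prediction error equals the torque
noise alone, which makes the torque-noise SD the irreducible RMSE floor of
any calibration and makes noiseless trials reproduce to machine precision.

A synthetic "subject" is drawn as multiplicative factors on the anatomical
initial values: F0m and φ0 two-sided (offset magnitude uniform in
[0.20, 0.45] and [0.10, 0.25] respectively, random sign), l0m uniform in
[0.88, 1.12], lst in [0.98, 1.02]. The two-sided draws guarantee every
subject differs appreciably from the anatomical set (a near-nominal
subject would leave calibration nothing to recover); the length draws are
narrow so the anatomical-initial forward run always stays feasible. All
draws lie inside the calibration bounds.

What passing tests on this data do **not** show: real sEMG envelopes have
amplitude nonstationarity, crosstalk between channels, and
electrode-placement effects that the bell-plus-noise model lacks; real
geometry is not exactly cubic; and real torque noise is not white.
Synthetic recovery results therefore demonstrate the correctness and
conditioning of the pipeline, not clinical accuracy.

## Evaluation

Trials are split per movement into calibration ("train") and held-out
("test") repetitions, mirroring a subjects-style split with parameter
draws as subjects. The headline quantity is the held-out torque RMSE
(reported in N·m; the units of the comparable published values are
unstated, which we flag). Per-muscle torque contributions `r_i·F_i` sum
exactly to the joint torque and are reported as signed series (fractions
are only meaningful when all contributions share a sign); reports also
carry mean activation per muscle and the clamp-event counts.

## Known limitations

* One DOF at a time; no coupled 3-D geometry, muscle wrapping, fatigue, or
  history dependence.
* The tendon-curve knee retains the small printed-constant discontinuity.
* The activation floor (0.01) slightly over-predicts resting muscle tone;
  with zero EMG a muscle still transmits ~1% of F0m.
* GA calibration is stochastic: at the reduced scale (population 40, 60
  generations) the held-out RMSE typically lands between 1.0× and 1.5× the
  torque-noise floor depending on the subject draw and GA seed, and the
  RMSE reduction relative to the anatomical initial parameters ranges
  roughly from 45% to 80% across seeds.
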
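# Methods

## The scientific problem

When a person's head is rotated passively on the stationary trunk and they
are asked to relax, the resistance measured at the head holder first rises
(the cervicocollic stretch reflex plus passive tissue and inertia) and then
subsides almost completely.  Two hypotheses compete for how this voluntary
suppression is achieved:

1. **Gain scheduling** — descending control simply scales the stretch-reflex
   loop gain toward zero.
2. **Neutralization (set-point servoing)** — peripheral *length* and *force*
   signals are fed back with opposing sign into the reflex servo, cancelling
   its output while leaving the loop armed.

The discriminating observation is that brief, unpredictable ramp-and-hold
perturbations delivered mid-course of the slow rotation still evoke
resistance: the reflex gain cannot have been set to zero.  `neckservo`
implements the neuromechanical model built around that observation, the
descriptive torque metrics, the constrained fitting/cross-validation
machinery, and a synthetic cohort generator that stands in for the human
recordings (which are not deposited anywhere).

## Plant model

The head is rigidly coupled to a position-controlled holder, so the
head-on-trunk kinematics θ(t), θ̇(t), θ̈(t) are *inputs*; the model is
evaluated open-loop.  All torques are expressed in the resistive-positive
orientation (torque opposing the imposed displacement is positive).  Net
torque is

    T_net(t) = J·θ̈(t)·π/180  +  K·θ(t) + B·θ̇(t)  +  T_reflex(t)  −  x(t)

with

* **Inertia** J = J_head + J_ecc.  The head is carried cantilevered and
  eccentric to the rotation axis, so beyond the anatomical head inertia
  (0.018 kg·m²) an eccentricity surplus (0.030 kg·m²) applies; for a sphere
  of mass m and radius r0 rotated about an axis offset r the moment is
  J = (2/5)·m·r0² + m·r² (`eccentric_inertia`).
* **Passive viscoelasticity** K = 0.008 Nm/°, B = 0.002 Nm·s/° (muscles,
  tendons, fasciae).
* **Reflex** — a PD controller standing in for the motoneuronal pool,
  T_reflex(t) = P·u(t−τ_c) + D·u̇(t−τ_c), with P = 0.09 Nm/°,
  D = 0.007 Nm·s/°, and a lumped loop delay τ_c = 50 ms.  Its input is
  u(t) = g·θ(t) − prop′(t), where g ∈ [0,1] is the reflex (gain-scheduling)
  factor and prop′ is the voluntary length feedback below.  u̇ is formed
  analytically from the velocity channel, never by differencing.
* **Length neutralization (prop′)** — when its switch is closed,
  prop′(t) = 0.9 · dz(θ(t − 70 ms), 0.6°), where dz(x, c) =
  sign(x)·max(|x|−c, 0) is a signed dead-zone.  This subtracts a delayed,
  thresholded copy of the displacement from the servo input ("set-point
  servoing").
* **Force neutralization (force′)** — when its switch is closed, the
  *measured* net torque (i.e. after the correction itself — the transducer
  signal) is delayed by 90 ms, dead-zoned at 0.02 Nm, and integrated with
  gain 4 s⁻¹: ẋ = 4 · dz(T_net(t − 90 ms), 0.02 Nm); x is subtracted from
  the net torque.  The stated unit (s⁻¹) admits only the pure-integrator
  reading 4/s.
* For the dynamic context (perturbations delivered mid-rotation) the length
  loop's delay is reduced to 50 ms and its gain raised to 1.1, exposed as
  `dynamic_suppression` / `DYNAMIC_OVERRIDE`.
* The vestibular pathway is omitted: at the ≤5°/s velocities used here the
  vestibulocollic contribution is negligible.

Counterfactual variants are expressed through `SwitchConfig`: `full` (both
loops), `force-only`, `length-only`, and `gain0` (loops open, reflex gain 0 —
pure gain scheduling, leaving the passive + inertial residual).

### Numerical scheme

Fixed-step forward-Euler evaluation at dt = 0.5 ms.  The inertial, passive
and reflex paths are feed-forward in the inputs and evaluated vectorized;
only the force-loop integrator is stateful (a JIT-compiled scalar loop with
a NumPy fallback).  Transport delays use fractional-sample linear
interpolation — rounding delays to the grid makes the fitting objective a
staircase in the delay parameters and demonstrably stalls the optimizer.
Halving dt from 1 ms to 0.5 ms moves the response integrals by ≈0.1%
(tested).  With delays zeroed and loops open the simulator reproduces the
closed-form second-order response J·s² + (B+D)·s + (K+P) exactly (tested on
0.1–5 Hz sinusoids).  Output is optionally decimated to 200 Hz to mirror the
acquisition rate.

Sign conventions and degenerate cases: degrees are used externally and
radians only where inertia enters; a zero input profile yields identically
zero torque; all loop buffers start at rest.

## Stimuli

* **Slow rotation** — raised-cosine position profile
  θ(t) = ±(A/2)(1 − cos(πt/T)), default 16° over 5 s.  The competing
  "smoothed trapezoid" reading is rejected because the raised cosine alone
  reproduces the stated ~5°/s peak velocity (16π/10 ≈ 5.03°/s): a true
  trapezoid with a 5°/s plateau cannot cover 16° in 5 s with smooth onsets.
* **Ramp-and-hold perturbations** — trapezoidal velocity pulses with linear
  rise/fall (constant acceleration; only rise time and plateau are
  specified, so linear segments are assumed).  The plateau velocity is
  solved from the displacement: standard 0.9°/0.4 s → 2.95°/s, fast
  1.8°/0.4 s → 5.90°/s, long 1.8°/0.65 s → 3.10°/s, all with a 90 ms rise.
  The final displacement is held after the pulse.
* **Superposition** — perturbation kinematics are added onto the slow
  rotation at 2.5 s (by then ≈8° are covered and the ongoing velocity is
  ≈5°/s), signed ipsilateral or contralateral.

## Metrics

* `torque_integrals` — trapezoidal integrals of net torque over [0, 100) ms
  (t1, "early") and [100, 300) ms (t2, "late") after perturbation onset,
  computed from the cumulative integral so the two windows are exactly
  contiguous (the conventional "101–300 ms" label reflects 5 ms sampling).
  Display scale 10⁻³ Nm·s.  For perturbations riding on the slow rotation
  the pre-onset torque is not zero (see limitations); an optional
  pre-onset-baseline subtraction is provided and used by the pipeline for
  dynamic conditions.
* `stiffness_curve` / `local_stiffness` — torque–displacement pairs over a
  window and their secant slope (Nm/°).
* `cumulative_abs_error` — ∫|T_sim − T_ref| dt.  The reported error
  functional lacks absolute-value bars but is described as a sum of
  *cumulative absolute* errors; the absolute value is adopted.
* `percent_of_static` — dynamic-context integrals as % of the static ones.

## Fitting and cross-validation

The objective is the summed cumulative absolute error of the three static
perturbation responses over 650 ms after onset (the window covers
post-stimulus relaxation even for the 0.4 s pulses).  Free parameters
default to 12 of the 13 constants: J_head is pinned because J_head and
J_ecc enter only through their sum and are not separately identifiable.
Bounds default to [0.2×, 5×] each nominal value (delays to [0.02, 0.15] s)
as a stand-in for the "physiological range" (no numeric bounds are
published).  Optimization is a bounded derivative-free local search in
bounds-normalized coordinates — Powell, then alternating Nelder–Mead/Powell
polish passes (the dead-zones create narrow correlated valleys that stall
either method alone) — with optional seeded Latin-hypercube multistart
(default 8) because the objective is non-convex.  Everything is
deterministic given the configured seed.

`cross_validate` runs the 3-fold leave-one-perturbation-out protocol:
fit on two static responses, predict the third; errors are reported as
percentages of the reference torque integral from onset to perturbation
end.  `compare_variants` fits each switch configuration independently
(dropping parameters its switches make inert) and ranks by total objective.

## Synthetic cohort

`generate_cohort` emulates six subjects measured at 200 Hz over the full
grid: 3 perturbation metrics × 3 contexts (static / dynamic ipsilateral /
dynamic contralateral) × 2 directions.  Ingredients:

* **Inter-subject variability** — lognormal multipliers (unit mean,
  CV 0.15) on every plant and suppression parameter; positivity is
  preserved by construction.  Jittered delays are snapped to the 0.5 ms
  integration grid.
* **Measurement noise** — white Gaussian noise low-passed at 30 Hz
  (4th-order Butterworth), added per trial; each condition cell is the
  average of 2 trials per direction, as in the acquisition protocol.
  `noise_sd` = 0.10 Nm per trial was fixed once by calibration: it is the
  log-least-squares optimum for matching all six tabulated between-subject
  SD columns of the static early/late integrals.  The stated CV of 0.15
  alone produces late-response dispersions about half the tabulated ones,
  so the noise absorbs the remainder; the effective noise on a 6-subject
  cohort-average trace is ≈ 0.10/√24 ≈ 0.02 Nm.
* The optional trial-discard rule (fluctuations beyond mean + 1.5 SD)
  mirrors the acquisition-time filter and is off by default.
* Dynamic cells are simulated with the dynamic-context length-loop
  override applied on top of each subject's jittered parameters.

What a green test on this generator does **not** establish: the synthetic
traces share the model's own functional form, so fits to them cannot probe
model misspecification; the noise is stationary and Gaussian, unlike real
torque drift and EMG-contaminated trials; and between-subject differences
in the real cohort are structured (e.g. anatomy vs strategy), not
independent lognormal jitter.

## Known limitations and honest failures

* **Standard-perturbation deceleration reversal.**  Experimentally, a fast
  oppositely-directed torque variation accompanies every deceleration
  phase.  The simulated net torque crosses zero for the fast and long
  perturbations but only dips to ≈ +0.013 Nm for the standard one: the
  inertial transient J·ω̇ ≈ 0.025 Nm is smaller than the ongoing resistive
  level.  The dip itself (≥ 80% of the inertial step) is reproduced for all
  three and tested; the sign-crossing acceptance test is left failing for
  the standard case rather than weakened.
* **Slow-rotation relaxation floor.**  The force loop's dead-zone threshold
  (0.02 Nm) bounds the mid-rotation residual from below at ≈ 0.02 Nm plus a
  tracking term (dT_raw/dt)/gain ≈ 0.02 Nm, while the same loop suppresses
  the earlier peak to ≈ 0.066 Nm.  The residual therefore cannot fall below
  10% of the trace's own peak (it is ≈ 60%), although it is far below the
  suppression-off torque at the same instant (≈ 0.04 vs 0.22 Nm, tested).
  On the scale of the recordings, whose peaks are several times larger, a
  0.02–0.04 Nm residual reads as "dropped to zero".
* **Weak identifiability under calibrated noise.**  With the calibrated
  noise, the passive stiffness K (torque share K·θ ≤ 0.014 Nm, below the
  effective noise) and the force-loop gain trade off along a flat ridge;
  their per-replicate optima wander widely and box-bound truncation biases
  the replicate means upward (K ≈ +84%, force gain ≈ +28%).  The noisy
  parameter-recovery acceptance test is left failing for those two
  parameters; the other ten recover with |bias| < 9%.  This mirrors the
  magnitude of the published cross-validation errors (18–34%).
* The closed-form damping ratio from the default parameters is 0.497; the
  published rounding is 0.51 (a 2–3% discrepancy attributed to parameter
  rounding, within the 5% acceptance tolerance).
* Closed-loop behaviour (voluntary head movement execution), Hill-type
  muscle models, EMG prediction, and the mixed-effects statistics on the
  response integrals are out of scope.
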
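# Methods

This note records the models implemented in `myodyn`, the parameter choices
that matter, the numerical decisions, and what the synthetic benchmark does
and does not establish.

## Signal conditioning

Raw sEMG (2 kHz, millivolts, six muscles: anterior/posterior deltoid,
biceps/triceps brachii, extensor/flexor carpi radialis) passes through, per
channel and in this order:

1. **Band-pass** 20–500 Hz, 4th-order Butterworth. sEMG energy lives in
   that band; the order is conventional practice (only the envelope
   smoother's order is dictated by the model, see below). At 2 kHz the
   500 Hz edge sits exactly at Nyquist, where no digital edge can be
   placed, so the upper edge is capped at 0.99 × Nyquist.
2. **Notch** at 50 Hz, second-order, quality factor 30 — power-line
   interference removal. Band-pass and notch act on the *raw* signal:
   rectification is nonlinear and would fold the interference into the
   baseband.
3. **Full-wave rectification** x ↦ |x|.
4. **Block sub-sampling**: the mean of |x| over non-overlapping blocks of
   N = 20 samples, aligning the 2 kHz sEMG with the 100 Hz angle stream.
   A trailing partial block is discarded (only complete blocks are
   defined).
5. **Envelope low-pass**: first-order Butterworth, cutoff 5 Hz, i.e.
   squared magnitude 1/(1 + (ω/ω_c)²) — joint motion is a low-frequency
   process. Small negative transients of this causal stage are clamped to
   zero to keep the envelope physically nonnegative.

All filters are **causal** (forward-only). The intended application is
real-time interaction control; zero-phase filtering would be non-causal.
Consequence: a digital causal realization matches the analog magnitude
prototype exactly at DC and (by pre-warping) at the cutoff, but deviates
from it near Nyquist — e.g. a 50 Hz probe at a 200 Hz rate sees gain 0.078
from the bilinear design versus 0.0995 from the analog formula. Tests pin
the response of the *designed digital* filter.

## Fuzzy-neural intention estimator

A zero-order (constant-consequent) Takagi–Sugeno system with one shared
rule base for the three outputs:

- inputs: 6-channel envelope, min–max normalized to [0, 1] (constant
  dimensions map to 0.5 under a scale guard);
- rule j, input i: center μ_ij = logistic(−(b_ij x_i + c_ij/(2σ_ij))),
  membership φ_ij = exp(−((x_i − μ_ij)/σ_ij)²);
- activation w_j = Π_i φ_ij over **all** inputs (every input feeds every
  rule), output y = Σ_j f_j w_j / Σ_j w_j, a convex combination of the
  rows of f (L × 3);
- predictions are de-normalized through the stored output statistics.

The grouping of the center exponent is read as b·x + c/(2σ); one
convention is used throughout. Activations are computed in log space with
the maximum subtracted before exponentiation, so far-out-of-domain inputs
never produce 0/0; the convex-hull property then holds for every finite
input.

**Training.** Full-batch gradient descent on the mean squared error in
normalized space, over (f, b, c); the widths σ stay at their
initialization (0.5 on the unit domain). Initialization is seeded: f as
small uniform noise around the normalized output mean, b and c from
N(0, 0.1) so every center starts near 0.5. Defaults: L = 10 rules,
learning rate 10.0, at most 1000 iterations, stop threshold 1e-10. Because
the loss is averaged over samples and outputs, its gradients are
batch-size-normalized; the rate was picked by a decade sweep (1/10/50 —
50 diverges, 1 is needlessly slow) and holds across the seeds exercised in
the tests. Gradients are verified against central finite differences to
1e-5 relative.

The estimator is **memoryless** — one envelope sample in, one angle sample
out. No lag embedding is used; this is the modelling choice the
whole-chain benchmark validates.

## Synthetic recordings

The generator emulates the acquisition setup the estimator targets
(six-muscle sEMG at 2 kHz, three joint angles at 100 Hz) so the chain can
be tested without clinical recordings:

- **Trajectories**: per joint, a sum of 3 sinusoids with periods drawn
  from 2–20 s, random amplitudes and phases, rescaled by the analytic
  amplitude bound into the physiological range (shoulder 0–90°, elbow
  0–120°, wrist ±60°). C¹-smooth with exact analytic derivatives.
- **Activation**: posture-driven. The drive is the joint's normalized
  excursion from mid-range; the agonist of each pair takes its positive
  part, the antagonist the negative part, on a tonic baseline of 0.1.
  Posture-proportional tonic activity is what slow sagittal
  flexion-extension against gravity predominantly produces, and it makes
  envelope → angle a well-posed memoryless map. (A velocity-driven mode
  exists for experiments; note that instantaneous velocity does not
  determine the angle, so that mode is *not* learnable by a memoryless
  estimator — an intrinsic property, not a defect of the fit.)
- **Raw sEMG**: activation (linearly upsampled to 2 kHz) × unit-RMS
  band-limited (20–500 Hz) Gaussian carrier, plus optional 50 Hz
  interference and a 1% white noise floor. Channel RMS therefore tracks
  activation level.

Defaults define the reference conditions: 100 s duration, baseline 0.1,
noise floor 0.01, no interference, seed-deterministic throughout (each
stage draws from an independent child stream of the seed).

**What the benchmark shows and what it does not.** Passing tests show the
pipeline recovers a pointwise envelope→angle relationship under realistic
band structure, rates and mild noise, and that the controller ranking is
as the theory predicts. Real sEMG adds nonstationarity, crosstalk,
electrode shift, fatigue and tremor, none of which are modeled; held-out
R² ≈ 0.98 on synthetic data is an upper bound of convenience, not a
clinical claim.

## Limb dynamics

Three-link planar serial chain (upper arm, forearm, hand) in the sagittal
plane; joint angles are relative, zero = hanging vertically. M(θ) is
assembled from center-of-mass Jacobians, C(θ, θ̇) from Christoffel symbols
(so Ṁ − 2C is skew-symmetric, verified to 1e-8), G(θ) as the potential
gradient (verified against finite differences of the energy). ∂M/∂θ uses
complex-step differentiation — exact to machine precision, no
step-size tuning. Link parameters default to standard adult anthropometry
(2.0 kg/0.30 m, 1.5 kg/0.25 m, 0.5 kg/0.18 m, COM at mid-length, rod
inertia ml²/12) and are fully configurable; the controllers use the model
structurally, not numerically. Public APIs take degrees (package-wide
convention); radians are internal.

## Controllers and simulator

The loop is kinematic: θ̇ = u + n, with the disturbance n entering at the
velocity level (deg/s). This follows the law's own units — the
"torque" of the zeroing design is dimensionally a velocity command. Gains
default to the study settings γ = 100 s⁻¹, λ = 200 s⁻², PID (10, 0.5,
0.2).

- ZNN: u = θ̇_d + γe, closed loop ė = −γe (general PD).
- NSZNN: u = θ̇_d + γe + λ∫e, closed loop ė = −γe − λ∫e (general PID).
  The discrete error sum is accumulated as Σe·Δt so that it discretizes
  the integral and λ keeps its stated value.
- GNN: u = γe — gradient descent on ½‖e‖², no feedforward; its steady lag
  on a ramp target is θ̇_d/γ.
- PID: error PID with backward-difference derivative and running-sum
  integral — inherently discrete-time.

**Integration.** The smooth laws are ODEs and are integrated by fixed-step
RK4 (default dt = 1 ms) with the disturbance sampled at each step start
and held; with this scheme the simulated ZNN decay matches e₀e^{−γt} to
~1e-9 relative at dt = 0.1 ms. Forward Euler is available
(`method="euler"`) and is visibly first-order (≈5% relative error under
the same conditions — useful as a discretization-error demonstration, not
as the default). The PID law always steps Euler, as a discrete controller.

**Disturbances.** constant c; ramp a·t (the unbounded case); random:
i.i.d. uniform per joint per step, by default on [0, r] — a bounded,
nonnegative disturbance whose mean the integral term suppresses, which is
what separates NSZNN from ZNN under random noise (a zero-mean white
disturbance moves both identically: the transfer s/(s² + γs + λ) has
white-noise power 1/(2γ) independent of λ). Bounds are configurable,
including the centered variant. Default magnitudes c = a = r = 1 deg/s.

**Comparisons** (`compare_controllers`, the `compare` CLI, the acceptance
experiment) start on the trajectory, θ(0) = θ_d(0), so the RMSE measures
disturbance response rather than the initial-value transient, and every
controller sees the identical disturbance stream. `simulate` itself
defaults to θ(0) = 0 for studying that transient. Closed-form oracles
(e₀e^{−γt}; steady states c/γ, 0, a/λ; growth slope a/γ) are implemented
separately from the simulator and cross-checked in the tests.

## Metrics

RMSE = sqrt(mean((θᵃ − θᵉ)²)) and R² = 1 − Var(θᵃ − θᵉ)/Var(θᵃ) with
population (1/Ω) variances. This variance-ratio R² is blind to a constant
offset between the series (unlike the sum-of-squares form) and may be
negative; both behaviours are documented and tested. R² requires a
non-constant reference series (a distinct error otherwise).

## Problem sizes

Reference runs: 100 s recordings (10 000 angle samples, 200 000 sEMG
samples), 80/20 chronological split; controller comparison on a 60 s
trajectory at dt = 1 ms (60 001 steps × 4 controllers × disturbance
kinds); oracle checks at dt = 0.1 ms over short horizons. These sizes keep
a full reproduction in the low minutes on one core while leaving every
steady-state measurement deep in its asymptotic regime.

## Known limitations

- The estimator is memoryless by design; movements whose sEMG→angle map is
  history-dependent (fatigue, co-contraction strategies) are out of scope.
- The torque-level closed loop is provided through the dynamics module but
  the primary loop is kinematic; human-robot interaction forces are not
  modeled.
- The synthetic generator's agonist/antagonist model is deliberately
  minimal (rectified posture drive); it does not emulate motor-unit
  statistics, Hill-type muscle dynamics, or tremor.
- Filter responses are those of causal digital realizations; analog
  magnitude prototypes are matched at DC and cutoff, not near Nyquist.
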
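# myodyn

Surface-EMG-driven motion-intention estimation and noise-suppressing
neural-dynamic tracking control for upper-limb rehabilitation robotics.

## The problem

Rehabilitation robots for the hemiparetic upper limb should follow the
patient's *own* intended movement. Two things make that hard. First, the
intention has to be read out in real time from noisy surface
electromyography (sEMG) over the six muscles driving the shoulder, elbow
and wrist in the sagittal plane. Second, the closed loop that tracks the
estimated trajectory is disturbed — by model error, friction, spasticity —
and the disturbance need not be bounded; a slowly ramping bias is the
dangerous case a clinical controller must absorb.

`myodyn` implements that full chain as a tested Python library:

1. **Envelope extraction** (`myodyn.preprocess`) — causal 20–500 Hz
   band-pass, 50 Hz power-line notch, full-wave rectification
   `x ↦ |x|`, block sub-sampling (mean of N=20 samples, 2 kHz → 100 Hz)
   and a first-order 5 Hz Butterworth smoother,
   |H(ω)|² = 1 / (1 + (ω/ω_c)^{2n}).
2. **Fuzzy-neural intention estimation** (`myodyn.afnn`) — a zero-order
   Takagi–Sugeno rule base mapping the 6-channel envelope x to the 3 joint
   angles. Rule j has Gaussian memberships
   φ_ij = exp(−((x_i − μ_ij)/σ_ij)²) with logistic, input-dependent
   centers μ_ij = 1/(1 + exp(b_ij x_i + c_ij/(2σ_ij))), and output
   y = Σ_j f_j Π_i φ_ij / Σ_j Π_i φ_ij — a convex combination of the
   consequent vectors f_j. Training is full-batch gradient descent on the
   normalized mean-squared error over (f, b, c).
3. **Neural-dynamic control** (`myodyn.control`) — the tracking loop
   θ̇ = u + n(t) with four laws:
   * **ZNN** (zeroing neural network) u = θ̇_d + γ(θ_d − θ), imposing
     ė = −γe — exponential convergence;
   * **NSZNN** (noise-suppressing ZNN) u = θ̇_d + γ(θ_d − θ) + λ∫e dt,
     imposing ė = −γe − λ∫e — rejects constant disturbances exactly and
     bounds a ramp a·t at a/λ;
   * **GNN** (gradient network) u = γ(θ_d − θ) and classical **PID** as
     baselines lacking the derivative feedforward.
4. **Limb model** (`myodyn.dynamics`) — a three-link planar Lagrangian
   chain M(θ)θ̈ + C(θ, θ̇)θ̇ + G(θ) = τ with anthropometric defaults, for
   torque-level reasoning about the same loop.
5. **Synthetic recordings** (`myodyn.synth`) — seeded generator of smooth
   3-joint trajectories and amplitude-modulated band-limited surrogate
   sEMG, so the whole chain is testable end to end without clinical data.
6. **Metrics** (`myodyn.evaluation`) — RMSE and the variance-ratio
   coefficient of determination R² = 1 − Var(θᵃ − θᵉ)/Var(θᵃ).

## Worked example

`examples/` contains one short script per capability. Running
`python examples/04_noise_rejection_laws.py` prints

```
ZNN decay vs e0*exp(-gamma t): max rel err 8.54e-10
ZNN residual under constant c=1:   0.01000  (c/gamma = 0.01000)
NSZNN residual, same disturbance:  5.34e-04  (suppressed)
NSZNN residual under ramp a=2:     0.01000  (a/lambda = 0.01000)
```

i.e. the simulated loop reproduces the analytic error laws: the ZNN error
decays like e₀e^{−γt} and is left with c/γ by a constant disturbance, while
the integral-enhanced law drives it back to zero and caps a ramp at a/λ.
`python examples/05_controller_comparison.py` tracks one synthetic movement
with all four controllers under an identical disturbance stream; under a
1 deg/s-scale constant disturbance it prints per-joint RMSEs

```
  pid    0.78074  1.04301  1.19099   (shoulder, elbow, wrist)
  gnn    0.08109  0.10565  0.12029
  znn    0.01000  0.01000  0.01000
  nsznn  0.00091  0.00091  0.00091
```

— the ordering NSZNN ≤ ZNN ≤ GNN ≤ PID that holds for every disturbance
kind. `python examples/03_intent_estimation.py` trains the estimator on a
synthetic session and scores the held-out 20% (R² ≈ 0.91–0.97 per joint).

There is also a thin CLI over the same functions:

```bash
myodyn synth --duration 30 --seed 42 --out data/
myodyn preprocess data/raw_emg.csv data/envelope.csv
myodyn train data/envelope.csv data/trajectory.csv data/model.json
myodyn compare data/trajectory.csv --noise linear
myodyn run --seed 42 --out run_out/   # full pipeline with manifest
```

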
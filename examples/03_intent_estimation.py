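"""Train the fuzzy-neural estimator: sEMG envelope -> three joint angles.

Fits the zero-order Takagi-Sugeno rule base by full-batch gradient descent
on the first 80% of a synthetic session and scores the chronologically
held-out 20%.  Per-joint RMSE is in degrees; R^2 near 1 means the estimated
motion intention explains almost all of the actual joint-angle variance.
"""

from myodyn import SynthConfig, make_dataset, process_recording
from myodyn.afnn import TrainConfig
from myodyn.pipeline import train_estimator

raw, traj = make_dataset(SynthConfig(duration=40.0, seed=42))
env = process_recording(raw)

model, history, report = train_estimator(
    env, traj, L=10, cfg=TrainConfig(maxstep=1000), train_fraction=0.8
)
print(f"training: {len(history)} iterations, MSE {history[0]:.4f} -> {history[-1]:.2e}")
print(f"held-out segment ({report['n_samples']} samples):")
for joint in report["rmse"]:
    print(f"  {joint:9s} RMSE {report['rmse'][joint]:6.2f} deg   R^2 {report['r_squared'][joint]:.4f}")
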
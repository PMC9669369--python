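"""Generate a synthetic movement session: joint angles + surrogate raw sEMG.

Builds 20 s of smooth shoulder/elbow/wrist flexion-extension inside
physiological ranges, derives six-muscle agonist/antagonist activations from
the posture, and modulates band-limited carriers into a 2 kHz raw sEMG
record.  Prints the shapes and per-channel RMS; the RMS tracks how strongly
each muscle is recruited over the session.
"""

import numpy as np

from myodyn import SynthConfig, make_dataset

cfg = SynthConfig(duration=20.0, seed=42)
raw, traj = make_dataset(cfg)

print(f"trajectory: {traj.n} samples at {traj.rate:g} Hz, joints {traj.table.channel_names}")
print(f"raw sEMG:   {raw.table.n} samples at {raw.rate:g} Hz, 6 muscles")
ang = traj.angles()
for j, joint in enumerate(traj.table.channel_names):
    print(f"  {joint:9s} range [{ang[:, j].min():7.2f}, {ang[:, j].max():7.2f}] deg")
for name in raw.table.channel_names:
    rms = np.sqrt(np.mean(raw.table.channel(name) ** 2))
    print(f"  {name:24s} RMS {rms:.3f} mV")
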
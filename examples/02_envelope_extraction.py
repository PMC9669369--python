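"""Extract the activation envelope from raw sEMG and check it against truth.

The conditioning chain (20-500 Hz band-pass, 50 Hz notch, rectification,
block sub-sampling to 100 Hz, 5 Hz low-pass) should recover each muscle's
activation profile up to a constant gain.  The printed correlation per
channel measures exactly that; values near 1 mean the envelope is a faithful
proxy for the generating activation.
"""

import numpy as np

from myodyn import SynthConfig, make_dataset, process_recording
from myodyn.synth import activation_from_kinematics, generate_trajectory

cfg = SynthConfig(duration=20.0, seed=42, interference_amp=0.2)
raw, traj = make_dataset(cfg)
env = process_recording(raw)

print(f"envelope: {env.table.n} samples at {env.rate:g} Hz (raw rate / 20)")
act = activation_from_kinematics(traj, cfg)
for name in env.table.channel_names:
    r = np.corrcoef(act.channel(name)[50:], env.table.channel(name)[50:])[0, 1]
    print(f"  {name:24s} corr(envelope, activation) = {r:.3f}")
print("(50 Hz interference was injected and removed by the notch stage)")
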
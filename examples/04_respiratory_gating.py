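"""Retrospective respiratory gating of the segmented FAIR acquisition.

The segmented readout is triggered at end-expiration but the 50-TI train
outlasts the quiescent window, so some k-space lines are acquired during
motion.  Gating flags those lines and replaces them with re-acquired
(motion-free) lines; this compares reconstruction error with and without.
"""

import numpy as np

from hepaflow import make_phantom, simulate_motion_study

phantom = make_phantom(matrix=64, resp_period_s=1.0, quiescent_fraction=0.6)
out = simulate_motion_study(phantom, mode="global", seed=0,
                            displacement_mm=2.0)

flags = out["flags"]
n = len(flags)
print(f"k-space lines acquired          : {n}")
print(f"lines flagged non-quiescent     : {flags.n_discarded} "
      f"({100 * flags.n_discarded / n:.0f}%)")

ref = out["reference"]
rms_ungated = np.sqrt(np.mean((out['ungated'] - ref) ** 2))
rms_gated = np.sqrt(np.mean((out['gated'] - ref) ** 2))
print(f"RMS error without gating        : {rms_ungated:10.3f} (signal units)")
print(f"RMS error with gating (reacquire): {rms_gated:10.3e}")
# Without gating, lines acquired during the 2 mm respiratory displacement
# ghost across the image; re-acquiring them restores the motion-free image
# to numerical precision.
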
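"""Estimate shoulder joint angles from simulated sensor quaternions.

Simulates one set of eight shoulder-flexion repetitions (0→90°) recorded
by trunk and upper-arm orientation sensors at 18 Hz with 2° orientation
noise, recovers the joint angles from the relative sensor rotation, and
compares them with the known ground truth.
"""

import numpy as np

import wearlimb as wl

spec = wl.MotionSpec(task="T1", repetitions=8)
noise = wl.NoiseSpec(orientation_sigma_deg=2.0, seed=7)
rec, truth = wl.simulate_recording(spec, noise)

shoulder = wl.shoulder_angles(rec.trunk_quat, rec.upperarm_quat, rec.timestamps)

err = shoulder.flexion - truth.shoulder.flexion
print(f"samples:                {len(rec)} at {rec.rate_hz:g} Hz")
print(f"peak flexion estimate:  {shoulder.flexion.max():.1f} deg (true 90.0)")
print(f"flexion RMSE vs truth:  {np.sqrt(np.mean(err**2)):.2f} deg")
print(f"gimbal-degenerate:      {int(shoulder.gimbal_flags.sum())} samples")
# The RMSE is the per-sample angle error induced by the 2-degree sensor
# orientation noise; noise-free recovery is exact by construction.
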
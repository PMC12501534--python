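# wearlimb

Upper-limb motion and grasp analysis for wearable sensor systems that
combine inertial orientation sensing (IMUs) with forearm force-sensing
resistor (FSR) arrays.

Such systems track workers' shoulder and elbow kinematics in real work
environments — ergonomic risk assessment, exoskeleton evaluation,
repetitive-task monitoring — where optical motion capture is impractical
and surface EMG is too fragile. `wearlimb` implements the complete
processing chain for a three-sensor configuration (trunk, upper arm,
forearm, each streaming a fused orientation quaternion at 18 Hz, with an
8-channel FSR band on each arm segment):

- **Joint angles.** The joint rotation is the relative rotation between
  adjacent segments' sensors: `q_shoulder = q_trunk* ⊗ q_upperarm` and
  `q_elbow = q_upperarm* ⊗ q_forearm` (Hamilton product, `*` the
  conjugate). Angles are read off with the intrinsic **Y-Z-X** Euler
  sequence: θ_y is flexion/extension (negated for the shoulder), θ_z
  ab/adduction, θ_x internal/external rotation. No sensor-to-segment
  calibration is required. Flexion velocity comes from the quaternion
  log-map: ω = 2·log(q_t* ⊗ q_{t+1})/Δt.
- **Grasp detection.** The eight forearm FSR channels are averaged;
  grasping produces signal bursts, and the local minima flanking each
  burst (no hand pressure, hand open) mark grasp onset and release
  offset. Burst peaks must exceed median + k·MAD; all thresholds scale
  with the signal.
- **Cycle analysis.** Movement cycles are segmented from the angle
  waveform (minima flanking each flexion maximum) or from grasp events,
  time-normalized to 80 points, and filtered against the pointwise median
  curve (cycles with Pearson r < 0.6 excluded). Per-cycle durations, ROM,
  and mean/peak angular velocities are summarized with mean, sample SD
  and the coefficient of variation CV = SD/mean.
- **Agreement statistics.** For validation against a 100 Hz reference
  system: linear upsampling, cross-correlation synchronization, per-cycle
  coefficient of multiple correlation

  CMC = √(1 − [Σ_g Σ_t (y_gt − ȳ_t)² / (T(G−1))] / [Σ_g Σ_t (y_gt − ȳ)² / (GT−1)]),

  RMSE, range-normalized RRMSE, and Bland–Altman bias ± 1.96 SD limits on
  per-cycle extrema.
- **Synthetic test bed.** A simulator generates ground-truth motions for
  a battery of standard validation tasks (isolated shoulder/elbow
  excursions, a sequenced flexion task, repetitive pick–carry–place work
  cycles), composes the corresponding sensor quaternion streams and FSR
  bursts with configurable noise, and exercises every stage above.

## Worked example

```python
import wearlimb as wl

spec = wl.MotionSpec(task="T1", repetitions=8)           # shoulder flexion 0–90°
noise = wl.NoiseSpec(orientation_sigma_deg=2.0, seed=7)  # 2° sensor noise
rec, truth = wl.simulate_recording(spec, noise)

shoulder = wl.shoulder_angles(rec.trunk_quat, rec.upperarm_quat, rec.timestamps)
```

Running `python examples/01_joint_angles_from_simulation.py` (the script
around the snippet above) prints:

```
samples:                577 at 18 Hz
peak flexion estimate:  96.2 deg (true 90.0)
flexion RMSE vs truth:  2.71 deg
gimbal-degenerate:      0 samples
```

— 8 repetitions at 18 Hz give 577 samples; the 2° orientation noise on
two sensors produces a per-sample angle error of about 2.7° RMS, and the
noisy peak overshoots the true 90° excursion accordingly. The other
scripts in `examples/` walk through grasp detection and timing scoring,
the full agreement pipeline (CMC/RMSE/RRMSE/Bland–Altman), and
worker-cycle segmentation and summary.

A thin CLI mirrors the library for shell pipelines:

```sh
wearlimb simulate --task T7 --reps 10 --seed 1 --out rec.csv --events truth_events.json
wearlimb angles --in rec.csv --joint shoulder --out angles.csv
wearlimb detect-grasp --in rec.csv --band lower --out events.json
wearlimb score-events --detected events.json --reference truth_events.json
```

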
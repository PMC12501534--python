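# Methods

This note documents the models, conventions and numerical choices behind
`wearlimb`, and what the synthetic test bed does and does not establish
about real recordings.

## Sensor model and conventions

The package assumes three body-worn orientation sensors — trunk (between
the shoulder blades), upper arm, forearm — whose on-board fusion outputs
a unit quaternion per sample, nominally at 18 Hz, plus an 8-channel FSR
band on each arm segment (raw unitless readings; the hardware's sensing
range corresponds to roughly 0.2–20 N). Each sensor's internal frame has
x pointing up, y along the frontal axis, z along the sagittal axis, so
rotation about y is flexion/extension, about z ab/adduction, about x
internal/external rotation.

Pinned conventions (the upstream hardware documentation leaves them
open, so they are package assumptions and are tested as such):

- **Hamilton quaternions, scalar-first** `(w, x, y, z)`, right-handed;
  `q` and `−q` are the same rotation everywhere.
- **Intrinsic Y-Z-X** Euler decomposition (body-fixed axes). The
  extrinsic reading was rejected because the axis semantics above are
  segment-fixed.
- Angles in degrees in every public interface; radians internal only.
- Right-arm sign convention: shoulder flexion = −θ_y, shoulder abduction
  = +θ_z, elbow flexion = +θ_y (the upper-arm and forearm sensors are
  mounted with aligned axes, so the elbow needs no negation).

## Joint angles

`q_joint = conj(q_proximal) ⊗ q_distal`, decomposed as above. Properties
the tests enforce: exact inversion of the synthetic composition
(noise-free closure below 1e-4°), and invariance to any rotation applied
commonly to all sensors (left-invariance), which is what makes the
system usable without heading alignment between sets.

**Gimbal lock.** At |θ_z| within 0.01° of 90° the outer angles are not
unique; the sample is flagged and reported under the convention θ_x := 0
with θ_y absorbing the defined part. Degenerate samples never raise, so
a long recording survives isolated lock samples. The lock branch uses
the numerically stable matrix entries (`atan2(R02, R22)`), not the
vanishing ones.

**No sensor-to-segment calibration** is applied by default; the intended
protocol is an N-pose alignment check before recording. An optional
static offset (mean over a user-marked still window, `npose_offset`) can
be subtracted explicitly.

**Angular velocity** is the forward difference of the quaternion
log-map, ω = 2·log(conj(q_t) ⊗ q_{t+1})/Δt, whose y component is the
flexion velocity of the joint proximal to the sensor's segment. The
series has length n−1, timestamped at the left sample. Forward
differencing is exact for constant-rate single-axis motion and its error
at 18 Hz (O(A·ω²·Δt)) is small relative to the sensor noise floor;
central differencing would halve the error at the cost of boundary
handling, and was not needed.

## Grasp detection

The eight forearm channels are averaged (the target movements engage the
whole forearm musculature; a spatial analysis is deliberately out of
scope). Detection: (1) moving-average smoothing, default 5 samples
(≈0.28 s at 18 Hz), used for peak finding only; (2) burst peaks must
exceed baseline + k·MAD (baseline = median, k = 3) and be separated by
≥ 1 s; (3) from each peak the detector walks outward **on the raw
averaged signal** to the first sample at or below baseline + m·MAD
(m = 1), then keeps descending to the local minimum — those minima are
grasp onset and release offset; (4) overlapping intervals merge; bursts
not closed by a minimum inside the record are discarded (complete events
only). Median/MAD rather than mean/SD keeps the baseline estimate valid
when bursts occupy much of the record. Because MAD degenerates to zero
on noise-free records (most samples exactly at baseline), the peak
threshold takes a floor of half the signal's excursion above baseline;
both terms scale with the signal, so detected event *times* are
invariant to positive rescaling. Walking on the raw rather than the
smoothed signal keeps noise-free onset/offset errors within one sample
period; smoothing would smear the burst edges by half the window.

**Timing scoring** matches detected to reference events greedily by
onset proximity (one-to-one, closest first) within half the median
reference cycle; onset errors score grasping and offset errors
releasing, signed as detected − reference. Relative errors are
percentages of the reference onset-to-onset interval containing the
event (the last event falls back to the median interval). Unmatched
events are counted as misses/false alarms and excluded from means.

## Cycle analysis

Waveform segmentation: prominent flexion maxima (default prominence 20°)
mark repetitions; prominence-filtered interior minima (default 10°) are
the boundaries; a cycle is a span between consecutive boundaries
containing at least one prominent maximum. Head and tail segments are
incomplete and dropped — a record of R back-to-back ramp-hold
repetitions yields R−2 interior complete cycles (R−1 for a continuous
oscillation whose first maximum precedes the first interior minimum).
Event-based segmentation uses consecutive grasp onsets (full work cycle)
or each event's onset→offset span (the "main event").

Each cycle is linearly resampled to 80 points spanning 0–100 % of the
cycle inclusive (endpoints exact; idempotent on 80-point curves). The
median representative curve is the pointwise median; cycles with Pearson
correlation below 0.6 against it are excluded and the median is
recomputed **once** over the survivors — a fixed two-pass scheme, not
iterated to convergence, since iteration can oscillate on small cycle
counts. A zero-variance cycle has undefined correlation and is excluded
with a distinct flag; at least one cycle always survives (best
correlation kept) so downstream summaries are never empty by filtering
alone. Pearson correlation was chosen as the standard waveform
similarity measure; rank correlations would be insensitive to the
amplitude changes the filter should catch.

Per-cycle parameters: duration from boundary timestamps; ROM = max − min
of the **raw** in-cycle samples (the 80-point curve would attenuate
extrema); mean and peak |ω_y|; the main-event duration from the grasp
event whose onset falls inside the cycle. Aggregates use the sample SD
(n−1) everywhere, and CV = 100·SD/mean, flagged undefined when the mean
is zero.

## Agreement statistics

- **Resampling**: linear interpolation onto a uniform grid at the target
  rate (default 100 Hz), endpoints preserved.
- **Synchronization**: integer-sample lag maximizing the normalized
  cross-correlation of mean-removed signals within ±max_lag (default
  1 s); ties break toward the smallest |lag|; no sub-sample refinement.
- **CMC**: within-protocol form for G = 2 waveforms; a negative radicand
  (between-waveform scatter exceeding total scatter, e.g. anti-phase
  curves) is reported as *undefined*, never clipped to 0, and undefined
  counts are surfaced in reports. Cycle-level CMCs are averaged
  arithmetically (no Fisher-z), keeping the summary on the familiar
  scale.
- **RRMSE**: RMSE normalized by the *reference* curve's range; the
  normalization choice matters and is pinned to the reference system so
  the denominator does not inherit wearable noise.
- **Bland–Altman**: bias = mean difference, limits = bias ± 1.96·sample
  SD, percentage of differences inside the closed interval; computed on
  per-cycle maxima and minima.

## Synthetic test bed

The generator defines the study conditions used throughout the tests:
raised-cosine ramp–hold–return excursions (C¹-smooth, extrema exactly at
the commanded amplitude), 8 repetitions per set, 4 s per repetition
(movements are self-paced in practice; 4 s is the package's one fixed
choice of a comfortable tempo), amplitudes 90° (160° for the high-flexion
task, performed with the trunk flexed 40°). The sequenced task orders
elbow-up → shoulder-up → elbow-down → shoulder-down with holds. Worker
cycles draw durations from N(period, CV·period) with CV = 5 % by default
(the consistency regime of steady repetitive packing work), a grasp
interval spanning a fixed lead-in plus 45 % of the cycle, and
flexion/elbow bumps time-locked to the grasp; FSR bursts are sin² bumps
per channel with ±20 % amplitude jitter over a 0.1 baseline, with
additive Gaussian noise (fraction of burst amplitude) clipped at zero.

Sensor composition inverts the kinematics exactly by construction
(rotations assembled in the same intrinsic YZX convention), so noise-free
closure isolates implementation error. Noise model: i.i.d. per-sample
small-angle multiplicative quaternion noise (right-multiplied,
body-frame), optional shared heading drift about the vertical
(left-multiplied, must cancel in joint angles), optional low-frequency
sinusoidal per-sensor wobble approximating soft-tissue artifact
(default off). All generators are seeded and bit-deterministic.

**What passing tests do not show**: the simulator has no magnetic
disturbance, no sensor-specific drift (drift is modelled as shared, the
cancelling case), no translation or impact artifacts, no FSR
creep/hysteresis, and its bursts are clean single-lobe bumps. Real
recordings will degrade the grasp detector and the angle estimates in
ways the closure tests cannot capture; the studies quantify behaviour
*under the stated noise model only*.

## Study sizes

The bundled studies use 10 virtual subjects × 6 tasks × 8 repetitions
for the laboratory validation, 20 seeds × 10 cycles for grasp timing,
and 10 seeds × 30 cycles for worker-cycle consistency — sizes chosen to
estimate means to well under their tolerance bands while keeping the
whole acceptance run in seconds on one CPU.

## Known limitations

- The YZX extraction is exercised mainly away from |θ_z| ≈ 90°;
  sustained abduction near 90° will produce many flagged samples whose
  θ_y/θ_x split is conventional.
- The relative timing-error denominator (reference onset-to-onset
  interval) is one of several defensible definitions; comparisons with
  other reports should check the denominator first.
- `segment_by_flexion` requires at least two prominent maxima and drops
  boundary repetitions by design; short records lose a larger fraction.
- The left/right arm distinction is a sign convention; only the
  right-arm convention is implemented.
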
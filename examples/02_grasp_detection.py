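"""Detect grasp/release events from forearm FSR bursts.

Simulates ten pick–carry–place work cycles with noisy FSR arrays, averages
the eight forearm channels, detects the bursts' delimiting minima as grasp
onset and release offset, and scores the timing against the true schedule.
"""

import wearlimb as wl

spec = wl.MotionSpec(task="worker_cycle", repetitions=10, seed=3)
noise = wl.NoiseSpec(fsr_sigma=0.05, seed=3)
rec, truth = wl.simulate_recording(spec, noise)

signal = wl.average_fsr(rec.fsr_lower)
events = wl.detect_grasps(signal, rec.timestamps)
report = wl.score_events(events, truth.schedule)

print(f"scheduled grasps: {len(truth.schedule)}, detected: {len(events)}, "
      f"matched: {report.n_matched}")
print(f"grasp-onset error:    {report.mean_onset_error_s:+.3f} s "
      f"({report.mean_onset_error_rel_pct:+.2f} % of the cycle)")
print(f"release-offset error: {report.mean_offset_error_s:+.3f} s "
      f"({report.mean_offset_error_rel_pct:+.2f} % of the cycle)")
# Signed errors are detected minus true times; the burst minima mark the
# moments of no hand pressure, so sub-0.1 s errors at 18 Hz mean the
# detector lands within one or two samples of the true grasp boundary.
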
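"""Cycle segmentation, time normalization, median filtering and summaries."""

import numpy as np
import pytest

import wearlimb as wl
from wearlimb.cycles import CycleSet
from wearlimb.datatypes import EventList, GraspEvent, JointAngleSeries


def _angles(t, flexion, joint="shoulder"):
    return JointAngleSeries(timestamps=t, flexion=flexion, joint=joint)


class TestSegmentByFlexion:
    def test_four_sinusoid_periods_three_cycles(self):
        # analytic extrema: minima at 3T/4 + kT, maxima at T/4 + kT
        T, rate = 4.0, 50.0
        t = np.arange(0, 4 * T, 1 / rate)
        x = 45 * np.sin(2 * np.pi * t / T)
        cs = wl.segment_by_flexion(_angles(t, x))
        assert cs.n_cycles == 3
        bounds_t = t[cs.boundaries]
        assert np.allclose(bounds_t, [3.0, 7.0, 11.0, 15.0], atol=1 / rate)

    def test_monotone_ramp_empty(self):
        t = np.arange(0, 10, 0.05)
        cs = wl.segment_by_flexion(_angles(t, 9 * t))
        assert cs.n_cycles == 0

    def test_half_amplitude_period_vs_prominence(self):
        """A weak repetition is kept or merged exactly as the prominence
        threshold dictates, verified against a brute-force extrema scan."""
        T, rate = 4.0, 50.0
        t = np.arange(0, 4 * T, 1 / rate)
        amp = np.where((t >= T) & (t < 2 * T), 12.0, 45.0)  # one weak period
        x = amp * np.sin(2 * np.pi * t / T) ** 2
        lo = wl.segment_by_flexion(_angles(t, x), wl.SegmentParams(
            max_prominence_deg=5.0, min_prominence_deg=2.0))
        hi = wl.segment_by_flexion(_angles(t, x), wl.SegmentParams(
            max_prominence_deg=20.0, min_prominence_deg=2.0))
        # brute force: count interior spans between consecutive minima that
        # contain a maximum exceeding the prominence threshold
        assert lo.n_cycles > hi.n_cycles
        for cs, thr in ((lo, 5.0), (hi, 20.0)):
            for a, b in cs.slices:
                assert x[a:b + 1].max() - min(x[a], x[b]) >= thr

    def test_determinism(self):
        t = np.arange(0, 16, 1 / 18)
        x = 45 * np.sin(2 * np.pi * t / 4)
        a = wl.segment_by_flexion(_angles(t, x))
        b = wl.segment_by_flexion(_angles(t, x))
        assert np.array_equal(a.slices, b.slices)
        assert np.array_equal(a.normalized_curves, b.normalized_curves)


class TestSegmentByEvents:
    def _series(self, dur=30.0, rate=18.0):
        t = np.arange(0, dur, 1 / rate)
        return _angles(t, np.sin(t))

    def test_event_to_event(self):
        ev = EventList(events=[GraspEvent(0.01, 2), GraspEvent(10, 12), GraspEvent(20, 22)])
        cs = wl.segment_by_events(self._series(), ev, mode="event_to_event")
        assert cs.n_cycles == 2
        assert np.allclose(cs.durations(), [10.0, 10.0], atol=1 / 18)

    def test_within_event(self):
        ev = EventList(events=[GraspEvent(2.0, 5.0)])
        cs = wl.segment_by_events(self._series(), ev, mode="within_event")
        assert cs.n_cycles == 1
        assert cs.durations()[0] == pytest.approx(3.0, abs=1 / 18)

    def test_event_outside_span_raises(self):
        ev = EventList(events=[GraspEvent(2.0, 50.0)])
        with pytest.raises(ValueError, match="outside"):
            wl.segment_by_events(self._series(dur=30.0), ev, mode="within_event")

    def test_sum_of_durations_bounded_by_recording(self):
        ev = EventList(events=[GraspEvent(0.01, 2), GraspEvent(10, 12), GraspEvent(25, 27)])
        s = self._series()
        cs = wl.segment_by_events(s, ev, mode="event_to_event")
        assert cs.durations().sum() <= s.timestamps[-1] - s.timestamps[0] + 1e-9


class TestTimeNormalize:
    def test_constant_curve(self):
        out = wl.time_normalize(np.full(33, 7.5))
        assert out.shape == (80,)
        assert np.allclose(out, 7.5)

    def test_linear_ramp_exact(self):
        out = wl.time_normalize(np.linspace(0, 79, 45), n_points=80)
        assert np.abs(out - np.linspace(0, 79, 80)).max() < 1e-9

    def test_sinusoid_within_interpolation_bound(self):
        m = 45
        x = np.sin(2 * np.pi * np.arange(m) / (m - 1))
        out = wl.time_normalize(x, 80)
        truth = np.sin(2 * np.pi * np.linspace(0, 1, 80))
        h = 1.0 / (m - 1)
        bound = (2 * np.pi) ** 2 * h**2 / 8  # max linear-interp error on sin
        assert np.abs(out - truth).max() <= bound + 1e-12

    def test_endpoints_preserved_and_idempotent(self, rng):
        x = rng.standard_normal(37)
        out = wl.time_normalize(x, 80)
        assert out[0] == x[0] and out[-1] == x[-1]
        assert np.abs(wl.time_normalize(out, 80) - out).max() < 1e-12

    def test_invalid_n_points(self):
        with pytest.raises(ValueError):
            wl.time_normalize(np.arange(10.0), n_points=1)


class TestMedianCurveFilter:
    def test_identical_cycles_nothing_excluded(self):
        c = np.tile(np.sin(np.linspace(0, 2 * np.pi, 80)), (5, 1))
        res = wl.median_curve_filter(c)
        assert np.all(res.included)
        assert np.allclose(res.median_curve, c[0])

    def test_inverted_cycle_excluded(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 80))
        c = np.vstack([np.tile(base, (5, 1)), -base])
        res = wl.median_curve_filter(c)
        assert not res.included[-1]
        assert res.correlations[-1] == pytest.approx(-1.0)
        assert np.all(res.included[:-1])

    def test_matches_brute_force_oracle(self, rng):
        c = rng.standard_normal((8, 80)).cumsum(axis=1)
        res = wl.median_curve_filter(c, r_min=0.6)
        # brute-force recomputation: pointwise median (even k: mean of the
        # middle two order statistics), Pearson per cycle
        k = len(c)
        med = np.array(
            [np.mean(sorted(c[:, j])[k // 2 - 1 : k // 2 + 1]) for j in range(80)]
        )
        r_bf = np.array([np.corrcoef(c[i], med)[0, 1] for i in range(k)])
        assert np.allclose(res.correlations, r_bf, atol=1e-12)
        if np.any(r_bf >= 0.6):
            assert np.array_equal(res.included, r_bf >= 0.6)

    def test_zero_variance_cycle_flagged_undefined(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 80))
        c = np.vstack([base, base, np.zeros(80)])
        res = wl.median_curve_filter(c)
        assert res.undefined[-1] and not res.included[-1]
        assert np.isnan(res.correlations[-1])

    def test_rmin_minus_one_excludes_none(self, rng):
        c = rng.standard_normal((6, 80)).cumsum(axis=1)
        res = wl.median_curve_filter(c, r_min=-1.0)
        assert np.all(res.included)

    def test_at_least_one_cycle_survives(self):
        a = np.sin(np.linspace(0, 2 * np.pi, 80))
        res = wl.median_curve_filter(np.vstack([a, -a]), r_min=0.99)
        assert res.included.sum() >= 1


class TestCycleParameters:
    def _cycleset(self, t, x, slices):
        slices = np.asarray(slices, int)
        curves = np.vstack([wl.time_normalize(x[a:b + 1], 80) for a, b in slices])
        return CycleSet(timestamps=t, values=x, slices=slices,
                        normalized_curves=curves,
                        included=np.ones(len(slices), bool), source_rate_hz=18.0)

    def test_constant_angle_zero_rom(self):
        t = np.arange(0, 30, 1 / 18)
        cs = self._cycleset(t, np.full_like(t, 3.0), [[0, 100], [100, 200]])
        summ = wl.cycle_parameters(cs)
        assert np.allclose(summ.per_cycle["rom_deg"], 0.0)
        assert summ.aggregate["duration_s"]["cv_pct"] == pytest.approx(0.0)

    def test_sinusoid_rom_and_peak_velocity(self):
        A, f, rate = 45.0, 0.25, 100.0
        t = np.arange(0, 12, 1 / rate)
        x = A * np.sin(2 * np.pi * f * t - np.pi / 2)  # starts at the minimum
        angles = _angles(t, x)
        cs = wl.segment_by_flexion(angles)
        q = wl.quaternions.from_euler_yzx(x, 0.0, 0.0)
        vel = wl.flexion_velocity(q, t)
        summ = wl.cycle_parameters(cs, velocity=vel)
        assert summ.n_cycles >= 1
        assert np.allclose(summ.per_cycle["rom_deg"], 2 * A, atol=0.1)
        peak_true = 2 * np.pi * f * A
        assert np.allclose(summ.per_cycle["peak_abs_vel_dps"], peak_true, rtol=0.02)

    def test_duration_cv_hand_calculation(self):
        # durations 9, 10, 11 s: sample SD = 1, mean = 10 -> CV = 10 %
        rate = 10.0
        t = np.arange(0, 40, 1 / rate)
        x = np.zeros_like(t)
        slices = [[0, 90], [90, 190], [190, 300]]
        cs = self._cycleset(t, x, slices)
        summ = wl.cycle_parameters(cs)
        assert summ.aggregate["duration_s"]["cv_pct"] == pytest.approx(10.0)

    def test_main_event_duration_from_events(self):
        t = np.arange(0, 30, 1 / 18)
        cs = self._cycleset(t, np.sin(t), [[0, 180], [180, 360]])
        ev = EventList(events=[GraspEvent(1.0, 4.0), GraspEvent(11.0, 13.5)])
        summ = wl.cycle_parameters(cs, events=ev)
        assert summ.per_cycle["main_event_s"].tolist() == pytest.approx([3.0, 2.5])

    def test_empty_when_nothing_included(self):
        t = np.arange(0, 30, 1 / 18)
        cs = self._cycleset(t, np.sin(t), [[0, 100]])
        cs.included[:] = False
        summ = wl.cycle_parameters(cs)
        assert summ.n_cycles == 0


def test_duration_cv_converges_to_generative_cv():
    """Estimated duration CV approaches the generator's CV as cycles grow."""
    est = []
    for seed in range(5):
        spec = wl.MotionSpec(task="worker_cycle", repetitions=40, duration_cv=0.08, seed=seed)
        truth = wl.generate_ground_truth(spec)
        rec = wl.compose_sensors(truth)
        sh = wl.shoulder_angles(rec.trunk_quat, rec.upperarm_quat, rec.timestamps)
        cs = wl.segment_by_events(sh, truth.schedule, mode="event_to_event")
        summ = wl.cycle_parameters(cs)
        est.append(summ.aggregate["duration_s"]["cv_pct"])
    assert abs(np.mean(est) - 8.0) < 1.5
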
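"""Agreement statistics: resampling, synchronization, CMC, RMSE, Bland–Altman."""

import numpy as np
import pytest

import wearlimb as wl


def cmc_brute_force(a, b):
    """Direct evaluation of the G=2 within-protocol CMC formula."""
    y = np.vstack([a, b])
    g, t = y.shape
    mean_t = y.mean(axis=0)
    grand = y.mean()
    num = sum((y[i, j] - mean_t[j]) ** 2 for i in range(g) for j in range(t)) / (t * (g - 1))
    den = sum((y[i, j] - grand) ** 2 for i in range(g) for j in range(t)) / (g * t - 1)
    if den == 0:
        return None
    rad = 1 - num / den
    return None if rad < 0 else np.sqrt(rad)


class TestResampleLinear:
    def test_constant(self):
        t = np.arange(0, 5, 1 / 18)
        tn, vn = wl.resample_linear(t, np.full_like(t, 3.3), 100.0)
        assert np.allclose(vn, 3.3)
        assert tn[0] == t[0]
        assert np.allclose(np.diff(tn), 0.01)

    def test_linear_ramp_exact(self):
        t = np.arange(0, 5, 1 / 18)
        tn, vn = wl.resample_linear(t, 2.0 * t + 1.0, 100.0)
        assert np.abs(vn - (2.0 * tn + 1.0)).max() < 1e-12

    def test_sinusoid_within_analytic_bound(self):
        f, A, rate = 1.0, 10.0, 18.0
        t = np.arange(0, 4, 1 / rate)
        tn, vn = wl.resample_linear(t, A * np.sin(2 * np.pi * f * t), 100.0)
        h = 1.0 / rate
        bound = h**2 * (2 * np.pi * f) ** 2 * A / 8
        assert np.abs(vn - A * np.sin(2 * np.pi * f * tn)).max() <= bound + 1e-12

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            wl.resample_linear(np.arange(5.0), np.arange(5.0), 0.0)


class TestSynchronize:
    def _sig(self, n=800, rate=100.0):
        t = np.arange(n) / rate
        return np.sin(2 * np.pi * 0.7 * t) + 0.3 * np.sin(2 * np.pi * 1.9 * t)

    def test_grid_multiple_shift_recovered_exactly(self):
        x = self._sig()
        shift = 37  # 0.37 s at 100 Hz: b is a delayed copy of a
        a = x[shift:]
        b = x[: len(x) - 0]  # b[j] = a[j - shift]
        lag, a_al, b_al = wl.synchronize(a, b, 100.0, max_lag_s=1.0)
        assert lag == pytest.approx(0.37)
        assert np.allclose(a_al, b_al)

    def test_zero_shift(self):
        x = self._sig()
        lag, a_al, b_al = wl.synchronize(x, x, 100.0, max_lag_s=1.0)
        assert lag == 0.0
        assert np.array_equal(a_al, b_al)

    def test_noisy_shift_within_one_sample_of_brute_force(self, rng):
        x = self._sig()
        shift = 21
        b = np.concatenate([np.zeros(shift), x])[: len(x)] + 0.05 * rng.standard_normal(len(x))
        lag, _, _ = wl.synchronize(x, b, 100.0, max_lag_s=1.0)
        # brute-force exhaustive integer-lag argmax of the cross-correlation
        a0, b0 = x - x.mean(), b - b.mean()
        best = max(
            range(-100, 101),
            key=lambda L: float(np.dot(a0[max(0, -L):len(a0) - max(0, L)],
                                       b0[max(0, L):len(b0) + min(0, L)])),
        )
        assert abs(lag * 100.0 - best) <= 1.0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            wl.synchronize(np.zeros(500), np.ones(500), 100.0, 1.0)


class TestCMC:
    def test_identical_waveforms_exactly_one(self):
        a = np.vstack([np.sin(np.linspace(0, 2 * np.pi, 80)), np.linspace(0, 1, 80)])
        values, undefined = wl.cmc(a, a.copy())
        assert np.all(values == 1.0)
        assert not np.any(undefined)

    def test_toy_offset_matches_formula_oracle(self):
        a = np.array([0.0, 10.0, 20.0])
        b = a + 2.0
        values, undefined = wl.cmc(a[None, :], b[None, :])
        oracle = cmc_brute_force(a, b)
        assert not undefined[0]
        assert values[0] == pytest.approx(oracle, abs=1e-14)
        # hand value: num = 2, den = 406/5 -> sqrt(1 - 2/81.2)
        assert values[0] == pytest.approx(np.sqrt(1 - 2 / 81.2), abs=1e-12)

    def test_antiphase_undefined(self):
        a = np.array([0.0, 10.0, 20.0])
        values, undefined = wl.cmc(a[None, :], -a[None, :])
        assert undefined[0] and np.isnan(values[0])

    def test_random_pairs_match_brute_force(self, rng):
        for _ in range(20):
            a = rng.standard_normal(12)
            b = rng.standard_normal(12)
            values, undefined = wl.cmc(a[None, :], b[None, :])
            oracle = cmc_brute_force(a, b)
            if oracle is None:
                assert undefined[0]
            else:
                assert values[0] == pytest.approx(oracle, abs=1e-12)

    def test_common_offset_invariance(self, rng):
        a = rng.standard_normal(40)
        b = a + 0.2 * rng.standard_normal(40)
        v1, _ = wl.cmc(a[None, :], b[None, :])
        v2, _ = wl.cmc(a[None, :] + 13.0, b[None, :] + 13.0)
        assert v1[0] == pytest.approx(v2[0], abs=1e-12)

    def test_labels(self):
        assert wl.cmc_label(0.96) == "excellent"
        assert wl.cmc_label(0.80) == "good"
        assert wl.cmc_label(float("nan")) == "undefined"


class TestRmseRrmse:
    def test_identical_zero(self):
        a = np.linspace(0, 90, 50)
        assert wl.rmse_rrmse(a, a) == (0.0, 0.0)

    def test_constant_offset(self):
        a = np.linspace(0, 90, 50)
        rmse, rrmse = wl.rmse_rrmse(a, a + 5.0)
        assert rmse == pytest.approx(5.0)
        assert rrmse == pytest.approx(100 * 5.0 / 90.0)

    def test_random_matches_brute_force(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        rmse, rrmse = wl.rmse_rrmse(a, b)
        bf = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 10)
        assert rmse == pytest.approx(bf, abs=1e-12)
        assert rrmse == pytest.approx(100 * bf / (a.max() - a.min()), abs=1e-12)

    def test_zero_range_rrmse_undefined(self):
        a = np.full(10, 5.0)
        rmse, rrmse = wl.rmse_rrmse(a, a + 1)
        assert rmse == pytest.approx(1.0)
        assert np.isnan(rrmse)

    def test_rmse_zero_iff_equal(self, rng):
        a = rng.standard_normal(20)
        b = a.copy()
        b[3] += 1e-6
        assert wl.rmse_rrmse(a, a)[0] == 0.0
        assert wl.rmse_rrmse(a, b)[0] > 0.0


class TestBlandAltman:
    def test_constant_offset_collapses_limits(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        ba = wl.bland_altman(a + 4.0, a)
        assert ba.bias == pytest.approx(4.0)
        assert ba.sd == 0.0
        assert ba.loa_lower == ba.loa_upper == pytest.approx(4.0)
        assert ba.pct_within == 100.0

    def test_hand_computed_toy(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 0.0])
        ba = wl.bland_altman(d, np.zeros(5))
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd == pytest.approx(np.sqrt(2.5))
        assert ba.loa_upper == pytest.approx(1.96 * np.sqrt(2.5))
        assert ba.pct_within == 100.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            wl.bland_altman(np.arange(2.0), np.arange(2.0))

    def test_normal_coverage_near_95(self):
        rng = np.random.default_rng(7)
        d = rng.standard_normal(10_000)
        ba = wl.bland_altman(d, np.zeros_like(d))
        assert 94.0 <= ba.pct_within <= 96.0


def test_compare_cycles_report_shape(rng):
    ref = np.vstack([np.sin(np.linspace(0, 2 * np.pi, 80)) * 45 for _ in range(5)])
    est = ref + rng.normal(0, 1.0, ref.shape)
    rep = wl.compare_cycles(ref, est)
    assert len(rep.cmc_values) == 5
    assert rep.mean_cmc > 0.95
    assert rep.mean_rmse < 3.0
    assert rep.ba_max is not None and rep.ba_min is not None
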
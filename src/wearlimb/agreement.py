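"""Agreement statistics between wearable and reference joint-angle series.

Covers the standard validation workflow against a gold-standard system:
linear upsampling of the 18 Hz wearable trace to the reference rate
(100 Hz), cross-correlation synchronization, per-cycle coefficient of
multiple correlation (CMC), RMSE, range-normalized RRMSE, and
Bland–Altman analysis of per-cycle extrema.

CMC here is the within-protocol form for G = 2 waveforms (wearable vs
reference) over T time points:

    CMC = sqrt(1 - [Σ_g Σ_t (y_gt - ȳ_t)² / (T·(G-1))]
                 / [Σ_g Σ_t (y_gt - ȳ)²  / (G·T - 1)])

with ȳ_t the across-waveform mean at time t and ȳ the grand mean.  A
negative radicand (between-waveform scatter exceeding overall scatter,
e.g. anti-phase waveforms) leaves the CMC undefined — reported as NaN
with a flag, never clipped to 0.  Interpretation bands commonly used for
kinematic waveforms: 0.75–0.84 good, 0.85–0.94 very good, >= 0.95
excellent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .datatypes import JointAngleSeries, ReferenceSeries

__all__ = [
    "resample_linear",
    "synchronize",
    "cmc",
    "cmc_label",
    "rmse_rrmse",
    "bland_altman",
    "BlandAltman",
    "AgreementReport",
]


def resample_linear(timestamps: np.ndarray, values: np.ndarray, target_hz: float):
    """Linear interpolation onto a uniform grid at ``target_hz`` spanning
    the original time range; endpoints preserved.  Returns (t_new, v_new)."""
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2 or len(t) != len(v):
        raise ValueError("need >= 2 samples with matching lengths")
    n = int(np.floor((t[-1] - t[0]) * target_hz)) + 1
    t_new = t[0] + np.arange(n) / target_hz
    return t_new, np.interp(t_new, t, v)


def resample_series(series, target_hz: float):
    """Resample a JointAngleSeries or ReferenceSeries; returns the same type."""
    if isinstance(series, ReferenceSeries):
        t, v = resample_linear(series.timestamps, series.values, target_hz)
        return ReferenceSeries(timestamps=t, values=v, rate_hz=target_hz, label=series.label)
    if isinstance(series, JointAngleSeries):
        t, flex = resample_linear(series.timestamps, series.flexion, target_hz)
        abd = None
        if series.abduction is not None:
            abd = np.interp(t, series.timestamps, series.abduction)
        flags = np.interp(t, series.timestamps, series.gimbal_flags.astype(float)) > 0
        return JointAngleSeries(
            timestamps=t, flexion=flex, abduction=abd, joint=series.joint, gimbal_flags=flags
        )
    raise TypeError(f"cannot resample {type(series).__name__}")


def synchronize(a: np.ndarray, b: np.ndarray, rate_hz: float, max_lag_s: float):
    """Time-align two uniform-rate signals by cross-correlation.

    Finds the integer-sample lag within ±``max_lag_s`` maximizing the
    normalized cross-correlation of the mean-removed signals (b lags a by
    +lag); returns ``(lag_s, a_aligned, b_aligned)`` with b shifted by
    −lag and overhanging samples trimmed.  No sub-sample refinement.
    Ties break toward the smallest |lag|.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("cannot synchronize a zero-variance signal")
    max_lag = int(round(max_lag_s * rate_hz))
    if min(len(a), len(b)) <= 2 * max_lag:
        raise ValueError("overlap too short for the requested max lag")

    a0 = a - a.mean()
    b0 = b - b.mean()
    full = sps.correlate(b0, a0, mode="full")  # index len(a)-1 <-> lag 0
    lags = np.arange(-len(a) + 1, len(b))
    mask = np.abs(lags) <= max_lag
    cc = full[mask]
    lag_cand = lags[mask]
    # stable tie-break: best correlation, then smallest |lag|
    order = np.lexsort((np.abs(lag_cand), -cc))
    lag = int(lag_cand[order[0]])

    if lag >= 0:
        a_al, b_al = a[: len(a) - 0], b[lag:]
    else:
        a_al, b_al = a[-lag:], b
    m = min(len(a_al), len(b_al))
    return lag / rate_hz, a_al[:m], b_al[:m]


def cmc(cycles_a: np.ndarray, cycles_b: np.ndarray):
    """Per-cycle coefficient of multiple correlation for two waveform sets.

    ``cycles_a``/``cycles_b`` are k×m arrays of matched cycles.  Returns
    ``(values, undefined)`` where ``values[f]`` is the CMC of cycle f (NaN
    when undefined) and ``undefined`` flags negative radicands or
    zero-variance pairs.
    """
    a = np.atleast_2d(np.asarray(cycles_a, dtype=float))
    b = np.atleast_2d(np.asarray(cycles_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"cycle arrays must match, got {a.shape} vs {b.shape}")
    k, m = a.shape
    values = np.full(k, np.nan)
    undefined = np.zeros(k, dtype=bool)
    for f in range(k):
        y = np.vstack([a[f], b[f]])  # G=2 waveforms × T points
        g, t = y.shape
        mean_t = y.mean(axis=0)
        grand = y.mean()
        num = np.sum((y - mean_t) ** 2) / (t * (g - 1))
        den = np.sum((y - grand) ** 2) / (g * t - 1)
        if den == 0.0:
            undefined[f] = True
            continue
        radicand = 1.0 - num / den
        if radicand < 0.0:
            undefined[f] = True
        else:
            values[f] = np.sqrt(radicand)
    return values, undefined


def cmc_label(value: float) -> str:
    """Conventional interpretation band for a CMC value (label, not logic)."""
    if np.isnan(value):
        return "undefined"
    if value >= 0.95:
        return "excellent"
    if value >= 0.85:
        return "very good"
    if value >= 0.75:
        return "good"
    return "poor"


def rmse_rrmse(reference: np.ndarray, estimate: np.ndarray):
    """RMSE (degrees) and range-normalized RRMSE (percent) of an estimated
    curve against a reference curve.

    RRMSE = 100·RMSE / (max(reference) − min(reference)).  A zero
    reference range leaves RRMSE undefined (NaN); RMSE is still returned.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1 or len(ref) < 2:
        raise ValueError("need two equal-length 1-D curves with >= 2 points")
    rmse = float(np.sqrt(np.mean((ref - est) ** 2)))
    rng = float(np.max(ref) - np.min(ref))
    rrmse = 100.0 * rmse / rng if rng > 0.0 else float("nan")
    return rmse, rrmse


@dataclass
class BlandAltman:
    """Bland–Altman agreement block for one per-cycle feature.

    ``bias`` is the mean difference a − b; limits of agreement are
    bias ± 1.96·SD (sample SD) and ``pct_within`` the percentage of
    differences inside the closed interval.  ``means``/``diffs`` are the
    paired plotting coordinates.
    """

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    pct_within: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(feat_a: np.ndarray, feat_b: np.ndarray) -> BlandAltman:
    """Bland–Altman analysis of paired per-cycle features (a − b)."""
    a = np.asarray(feat_a, dtype=float)
    b = np.asarray(feat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired features must be equal-length 1-D arrays")
    if len(a) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(100.0 * np.mean((d >= lo) & (d <= hi)))
    return BlandAltman(
        bias=bias, sd=sd, loa_lower=lo, loa_upper=hi, pct_within=within,
        means=(a + b) / 2.0, diffs=d,
    )


@dataclass
class AgreementReport:
    """Per-cycle CMC/RMSE/RRMSE plus Bland–Altman blocks on cycle extrema."""

    cmc_values: np.ndarray
    cmc_undefined: np.ndarray
    rmse_deg: np.ndarray
    rrmse_pct: np.ndarray
    ba_max: BlandAltman | None = None
    ba_min: BlandAltman | None = None
    sync_lag_s: float = 0.0

    @property
    def mean_cmc(self) -> float:
        defined = self.cmc_values[~self.cmc_undefined]
        return float(np.mean(defined)) if len(defined) else float("nan")

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse_deg))

    @property
    def mean_rrmse(self) -> float:
        vals = self.rrmse_pct[np.isfinite(self.rrmse_pct)]
        return float(np.mean(vals)) if len(vals) else float("nan")

    @property
    def n_cmc_undefined(self) -> int:
        return int(np.sum(self.cmc_undefined))


def compare_cycles(ref_cycles: np.ndarray, est_cycles: np.ndarray, sync_lag_s: float = 0.0) -> AgreementReport:
    """Full per-cycle agreement report for matched k×m cycle arrays.

    Cycle-level CMC/RMSE/RRMSE (reference range in the RRMSE denominator)
    plus Bland–Altman on the per-cycle maxima and minima (reference −
    estimate) when k >= 3.
    """
    ref = np.atleast_2d(np.asarray(ref_cycles, dtype=float))
    est = np.atleast_2d(np.asarray(est_cycles, dtype=float))
    if ref.shape != est.shape:
        raise ValueError("cycle arrays must have identical shape")
    values, undefined = cmc(ref, est)
    rmse = np.empty(len(ref))
    rrmse = np.empty(len(ref))
    for f in range(len(ref)):
        rmse[f], rrmse[f] = rmse_rrmse(ref[f], est[f])
    ba_max = ba_min = None
    if len(ref) >= 3:
        ba_max = bland_altman(ref.max(axis=1), est.max(axis=1))
        ba_min = bland_altman(ref.min(axis=1), est.min(axis=1))
    return AgreementReport(
        cmc_values=values, cmc_undefined=undefined, rmse_deg=rmse, rrmse_pct=rrmse,
        ba_max=ba_max, ba_min=ba_min, sync_lag_s=sync_lag_s,
    )
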
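"""Movement-cycle segmentation, time normalization and cycle statistics.

A repetitive task (repeated flexion, pick–carry–place) is split into
cycles either from the joint-angle waveform itself (minima flanking the
flexion maxima) or from grasp events; each cycle is resampled to 80 points
(0–100 % of the cycle), a median representative curve is built, cycles
poorly correlated with the median (Pearson r < 0.6 by default) are
excluded as outliers, and per-cycle parameters (durations, range of
motion, angular velocities) are summarized with mean, sample SD and the
coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datatypes import AngularVelocitySeries, EventList, JointAngleSeries

__all__ = [
    "SegmentParams",
    "CycleSet",
    "CycleSummary",
    "MedianFilterResult",
    "segment_by_flexion",
    "segment_by_events",
    "time_normalize",
    "median_curve_filter",
    "cycle_parameters",
]

logger = logging.getLogger(__name__)

N_POINTS_DEFAULT = 80  # 0-100 % of the cycle
R_MIN_DEFAULT = 0.6


@dataclass
class SegmentParams:
    """Tunables for waveform-based segmentation.

    max_prominence_deg : prominence a flexion maximum must exceed to count
        as a task repetition (default 20°).
    min_prominence_deg : prominence filter on the delimiting minima
        (default 10°), suppressing noise wiggles inside holds.
    n_points : length of the time-normalized cycle curves.
    """

    max_prominence_deg: float = 20.0
    min_prominence_deg: float = 10.0
    n_points: int = N_POINTS_DEFAULT


@dataclass
class CycleSet:
    """k movement cycles over one angle series.

    ``slices`` holds (start, end) sample indices per cycle, end inclusive;
    consecutive cycles share endpoints when segmentation is contiguous
    (waveform- or onset-to-onset event-based), in which case ``boundaries``
    exposes the k+1 boundary chain.  ``normalized_curves`` is k×n_points,
    each row one cycle resampled to 0–100 %.
    """

    timestamps: np.ndarray
    values: np.ndarray
    slices: np.ndarray  # (k, 2) int
    normalized_curves: np.ndarray  # (k, n_points)
    included: np.ndarray  # (k,) bool
    source_rate_hz: float

    @property
    def n_cycles(self) -> int:
        return len(self.slices)

    @property
    def boundaries(self) -> np.ndarray:
        """k+1 boundary indices; only defined for contiguous segmentations."""
        if self.n_cycles == 0:
            return np.array([], dtype=int)
        if not np.all(self.slices[1:, 0] == self.slices[:-1, 1]):
            raise ValueError("cycle set is not contiguous; use .slices")
        return np.concatenate([self.slices[:, 0], self.slices[-1:, 1]])

    def durations(self) -> np.ndarray:
        """Per-cycle duration in seconds from boundary timestamps."""
        return self.timestamps[self.slices[:, 1]] - self.timestamps[self.slices[:, 0]]


def _empty_cycleset(angles: JointAngleSeries, n_points: int, rate: float) -> CycleSet:
    return CycleSet(
        timestamps=angles.timestamps,
        values=angles.flexion,
        slices=np.zeros((0, 2), dtype=int),
        normalized_curves=np.zeros((0, n_points)),
        included=np.zeros(0, dtype=bool),
        source_rate_hz=rate,
    )


def _build_cycleset(
    angles: JointAngleSeries, slices: np.ndarray, n_points: int, channel: np.ndarray
) -> CycleSet:
    rate = (len(angles) - 1) / (angles.timestamps[-1] - angles.timestamps[0])
    curves = np.vstack(
        [time_normalize(channel[a : b + 1], n_points) for a, b in slices]
    ) if len(slices) else np.zeros((0, n_points))
    return CycleSet(
        timestamps=angles.timestamps,
        values=channel,
        slices=np.asarray(slices, dtype=int).reshape(-1, 2),
        normalized_curves=curves,
        included=np.ones(len(slices), dtype=bool),
        source_rate_hz=rate,
    )


def segment_by_flexion(
    angles: JointAngleSeries,
    params: SegmentParams | None = None,
    channel: str = "flexion",
) -> CycleSet:
    """Segment a repetitive task from its angle waveform.

    Prominent flexion maxima mark repetitions; the local minima flanking
    them delimit the cycles.  Concretely: boundaries are the interior
    local minima of the waveform (prominence-filtered), and a cycle is any
    span between consecutive boundaries that contains at least one
    prominent maximum.  Head and tail segments outside the outermost
    boundaries are incomplete and dropped, so a record of R back-to-back
    repetitions yields the R−2 interior complete cycles (R−1 for a
    continuous oscillation whose first maximum precedes the first interior
    minimum).  Fewer than 2 prominent maxima yields an empty set with a
    warning, not an error.
    """
    params = params or SegmentParams()
    x = angles.flexion if channel == "flexion" else angles.abduction
    if x is None:
        raise ValueError(f"series has no {channel!r} channel")
    rate = (len(angles) - 1) / (angles.timestamps[-1] - angles.timestamps[0])

    maxima, _ = sps.find_peaks(x, prominence=params.max_prominence_deg)
    if len(maxima) < 2:
        logger.warning("fewer than 2 prominent flexion maxima; empty cycle set")
        return _empty_cycleset(angles, params.n_points, rate)

    minima, _ = sps.find_peaks(-x, prominence=params.min_prominence_deg)
    if len(minima) < 2:
        logger.warning("fewer than 2 delimiting minima; empty cycle set")
        return _empty_cycleset(angles, params.n_points, rate)

    slices = []
    for a, b in zip(minima[:-1], minima[1:]):
        if np.any((maxima > a) & (maxima < b)):
            slices.append((a, b))
    if not slices:
        return _empty_cycleset(angles, params.n_points, rate)
    return _build_cycleset(angles, np.asarray(slices), params.n_points, x)


def segment_by_events(
    angles: JointAngleSeries,
    events: EventList,
    mode: str = "event_to_event",
    n_points: int = N_POINTS_DEFAULT,
) -> CycleSet:
    """Segment an angle series at grasp events.

    ``event_to_event``: cycle boundaries at consecutive event onsets — the
    full work cycle between two consecutive pack/place actions.
    ``within_event``: one cycle per event spanning onset→offset — the
    "main event" during which the load is held.
    """
    if mode not in ("event_to_event", "within_event"):
        raise ValueError(f"unknown mode {mode!r}")
    t = angles.timestamps
    times: list[tuple[float, float]]
    if mode == "event_to_event":
        if len(events) < 2:
            raise ValueError("event_to_event needs at least 2 events")
        on = events.onsets
        times = list(zip(on[:-1], on[1:]))
    else:
        if len(events) < 1:
            raise ValueError("within_event needs at least 1 event")
        times = [(e.onset, e.offset) for e in events]

    for a, b in times:
        if a < t[0] - 1e-9 or b > t[-1] + 1e-9:
            raise ValueError(
                f"event span ({a}, {b}) outside angle series span ({t[0]}, {t[-1]})"
            )

    idx = lambda v: int(np.argmin(np.abs(t - v)))
    slices = np.array([(idx(a), idx(b)) for a, b in times], dtype=int)
    if np.any(slices[:, 0] >= slices[:, 1]):
        raise ValueError("an event collapses to fewer than 2 samples at this rate")
    return _build_cycleset(angles, slices, n_points, angles.flexion)


def time_normalize(curve: np.ndarray, n_points: int = N_POINTS_DEFAULT) -> np.ndarray:
    """Linear resampling of one cycle onto ``n_points`` equally spaced
    abscissae spanning 0–100 % inclusive; endpoints preserved exactly."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or len(curve) < 2:
        raise ValueError("curve must be 1-D with length >= 2")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    src = np.linspace(0.0, 100.0, len(curve))
    dst = np.linspace(0.0, 100.0, n_points)
    return np.interp(dst, src, curve)


@dataclass
class MedianFilterResult:
    """Outcome of the median-curve outlier filter."""

    median_curve: np.ndarray
    included: np.ndarray  # bool per cycle
    correlations: np.ndarray  # nan where undefined
    undefined: np.ndarray  # bool: zero-variance cycle, correlation undefined


def median_curve_filter(
    curves: np.ndarray, r_min: float = R_MIN_DEFAULT
) -> MedianFilterResult:
    """Pointwise median representative curve with outlier exclusion.

    Pearson correlation of each cycle with the pointwise median across
    cycles; cycles with r < ``r_min`` are excluded (removing non-standard
    movements), and the median is recomputed ONCE over the survivors —
    two passes, fixed, not iterated to convergence.  A zero-variance cycle
    has undefined correlation and is excluded with a distinct flag.  At
    least one cycle always survives: if the rule would exclude all, the
    best-correlated cycle is kept.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need a k×m array with k >= 2 cycles")
    k = curves.shape[0]

    median0 = np.median(curves, axis=0)
    med_sd = np.std(median0)
    corr = np.full(k, np.nan)
    undefined = np.zeros(k, dtype=bool)
    for i in range(k):
        sd = np.std(curves[i])
        if sd == 0.0 or med_sd == 0.0:
            undefined[i] = True
        else:
            corr[i] = np.corrcoef(curves[i], median0)[0, 1]

    included = ~undefined & (corr >= r_min)
    if not np.any(included):
        defined = np.flatnonzero(~undefined)
        keep = defined[np.argmax(corr[defined])] if len(defined) else 0
        included[keep] = True

    median1 = np.median(curves[included], axis=0)
    return MedianFilterResult(
        median_curve=median1, included=included, correlations=corr, undefined=undefined
    )


@dataclass
class CycleSummary:
    """Per-cycle parameters and their aggregates.

    ``per_cycle`` columns: cycle, duration_s, main_event_s, rom_deg,
    mean_abs_vel_dps, peak_abs_vel_dps.  ``aggregate`` maps each parameter
    to (mean, sd, cv_pct); sample SD (ddof=1); CV = 100·SD/mean, NaN
    (undefined) when the mean is 0.
    """

    per_cycle: pd.DataFrame
    aggregate: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.per_cycle)


_PARAM_COLS = ("duration_s", "main_event_s", "rom_deg", "mean_abs_vel_dps", "peak_abs_vel_dps")


def cycle_parameters(
    cycleset: CycleSet,
    velocity: Optional[AngularVelocitySeries] = None,
    events: Optional[EventList] = None,
) -> CycleSummary:
    """Per-cycle durations, ROM and angular-velocity statistics.

    ROM is max − min of the *raw* in-cycle samples (not the 80-point
    resampled curve, which would attenuate extrema).  The main-event
    duration of a cycle is the duration of the grasp event whose onset
    falls inside the cycle (NaN when no events are given or none falls
    inside).  Velocity statistics are mean and max of |omega_y| over the
    velocity samples inside the cycle.  Only included cycles enter;
    aggregates report mean, sample SD and CV in percent.
    """
    rows = []
    t = cycleset.timestamps
    for ci in np.flatnonzero(cycleset.included):
        a, b = cycleset.slices[ci]
        t0, t1 = t[a], t[b]
        seg = cycleset.values[a : b + 1]
        row = {
            "cycle": int(ci),
            "duration_s": float(t1 - t0),
            "rom_deg": float(np.max(seg) - np.min(seg)),
            "main_event_s": np.nan,
            "mean_abs_vel_dps": np.nan,
            "peak_abs_vel_dps": np.nan,
        }
        if events is not None:
            for e in events:
                if t0 - 1e-9 <= e.onset < t1:
                    row["main_event_s"] = e.duration
                    break
        if velocity is not None:
            mask = (velocity.timestamps >= t0) & (velocity.timestamps < t1)
            if np.any(mask):
                w = np.abs(velocity.omega_y[mask])
                row["mean_abs_vel_dps"] = float(np.mean(w))
                row["peak_abs_vel_dps"] = float(np.max(w))
        rows.append(row)

    if not rows:
        logger.warning("no included cycles; empty summary")
        return CycleSummary(per_cycle=pd.DataFrame(columns=("cycle",) + _PARAM_COLS))

    df = pd.DataFrame(rows)
    aggregate = {}
    for col in _PARAM_COLS:
        vals = df[col].dropna().to_numpy()
        if len(vals) == 0:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0.0 else float("nan")
        aggregate[col] = {"mean": mean, "sd": sd, "cv_pct": cv}
    return CycleSummary(per_cycle=df, aggregate=aggregate)
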
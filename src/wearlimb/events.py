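"""Grasp/release event detection from forearm FSR arrays and timing scoring.

During a grasp-and-carry action the wrist and finger flexors bulge into
the forearm band, producing a burst in the force-sensing resistors.  The
eight channels are averaged (the target movement engages the whole
forearm, so no spatial analysis is needed); a burst's flanking local
minima — where no pressure is applied and the hand is open — mark grasp
onset and release offset.

The burst-finding mechanism (moving-average smoothing, median/MAD
thresholds, minimum peak gap) is a robust default, fully configurable via
:class:`DetectorParams`.  Median/MAD is used instead of mean/SD so the
baseline estimate survives bursts occupying much of the record.  All
thresholds scale with the signal, so detected event *times* are invariant
to positive rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .datatypes import EventList, GraspEvent, ReferenceSeries

__all__ = [
    "DetectorParams",
    "average_fsr",
    "detect_grasps",
    "score_events",
    "reference_events_from_trajectory",
    "TimingErrorReport",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectorParams:
    """Tunables of the FSR burst detector.

    smooth_window : moving-average width in samples (default 5 ≈ 0.28 s at
        18 Hz) applied before peak finding only; the minima walk runs on
        the raw averaged signal so event times are not smeared.
    k_peak : peak threshold = baseline + k_peak·MAD (baseline = median).
    m_min : minima threshold = baseline + m_min·MAD.
    min_gap_s : minimum separation between burst peaks, seconds.
    peak_floor_frac : fraction of (max - baseline) used as a floor for the
        peak threshold when MAD degenerates to 0 (noise-free records where
        most samples sit exactly at baseline); scale-equivariant.
    """

    smooth_window: int = 5
    k_peak: float = 3.0
    m_min: float = 1.0
    min_gap_s: float = 1.0
    peak_floor_frac: float = 0.5

    def validate(self) -> "DetectorParams":
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.min_gap_s <= 0:
            raise ValueError("min_gap_s must be positive")
        return self


def average_fsr(channels: np.ndarray) -> np.ndarray:
    """Per-sample arithmetic mean across the 8 FSR channels of one band."""
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2 or channels.shape[1] != 8:
        raise ValueError(f"expected an n×8 FSR array, got shape {channels.shape}")
    if not np.all(np.isfinite(channels)):
        raise ValueError("FSR channels contain non-finite values")
    return channels.mean(axis=1)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.copy()
    kernel = np.ones(width) / width
    # reflect-pad so the smoothed record keeps length n without edge bias
    pad_l = width // 2
    pad_r = width - 1 - pad_l
    padded = np.concatenate([x[pad_l:0:-1], x, x[-2 : -2 - pad_r : -1]])
    return np.convolve(padded, kernel, mode="valid")


def _walk_to_minimum(x: np.ndarray, start: int, thr: float, step: int) -> int | None:
    """From ``start``, move in direction ``step`` to the first sample at or
    below ``thr``, then keep descending while the next sample is strictly
    lower.  Returns None when the record edge is reached before the signal
    drops below the threshold (burst not closed by a minimum)."""
    i = start
    n = len(x)
    while x[i] > thr:
        nxt = i + step
        if nxt < 0 or nxt >= n:
            return None
        i = nxt
    while True:
        nxt = i + step
        if nxt < 0 or nxt >= n or x[nxt] >= x[i]:
            return i
        i = nxt


def detect_grasps(
    signal: np.ndarray,
    timestamps: np.ndarray,
    params: DetectorParams | None = None,
) -> EventList:
    """Detect grasp intervals as the minima flanking bursts of the averaged
    forearm FSR signal.

    Pipeline: (1) smooth with a moving average; (2) find burst peaks above
    baseline + k·MAD separated by at least ``min_gap_s``; (3) from each
    peak walk backward/forward on the *raw* signal to the nearest local
    minimum below baseline + m·MAD — those minima are onset and offset;
    (4) merge events whose intervals overlap.  Bursts not closed by a
    minimum inside the record are discarded (only complete events count).

    An all-constant signal yields an empty list, not an error.
    """
    params = (params or DetectorParams()).validate()
    x = np.asarray(signal, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if x.ndim != 1 or len(x) != len(t):
        raise ValueError("signal and timestamps must be 1-D of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")

    if np.ptp(x) == 0.0:
        return EventList(events=[], source="fsr")

    rate = (len(t) - 1) / (t[-1] - t[0])
    smoothed = _moving_average(x, params.smooth_window)

    baseline = float(np.median(x))
    mad = float(np.median(np.abs(x - baseline)))
    thr_peak = baseline + max(
        params.k_peak * mad, params.peak_floor_frac * (float(np.max(x)) - baseline)
    )
    thr_min = baseline + params.m_min * mad

    distance = max(1, int(round(params.min_gap_s * rate)))
    peaks, _ = sps.find_peaks(smoothed, height=thr_peak, distance=distance)

    intervals: list[tuple[int, int, float]] = []
    for p in peaks:
        onset = _walk_to_minimum(x, p, thr_min, step=-1)
        offset = _walk_to_minimum(x, p, thr_min, step=+1)
        if onset is None or offset is None or onset >= offset:
            continue  # burst touches the record boundary: incomplete
        intervals.append((onset, offset, float(x[onset:offset + 1].max())))

    # merge overlapping intervals (two peaks sharing one burst)
    merged: list[tuple[int, int, float]] = []
    for iv in sorted(intervals):
        if merged and iv[0] <= merged[-1][1]:
            a, b, pk = merged[-1]
            merged[-1] = (a, max(b, iv[1]), max(pk, iv[2]))
        else:
            merged.append(iv)

    events = [
        GraspEvent(onset=float(t[a]), offset=float(t[b]), peak_value=pk)
        for a, b, pk in merged
    ]
    return EventList(events=events, source="fsr")


@dataclass
class TimingErrorReport:
    """Signed timing errors (detected − reference) for matched event pairs.

    Onset errors score grasping, offset errors score releasing.  Relative
    errors are percentages of the reference cycle duration (onset-to-onset
    interval; the last event uses the median interval).  Unmatched
    reference events are misses; unmatched detected events are false
    alarms; neither enters the means.
    """

    onset_errors_s: np.ndarray
    offset_errors_s: np.ndarray
    onset_errors_rel_pct: np.ndarray
    offset_errors_rel_pct: np.ndarray
    n_matched: int
    n_missed: int
    n_false_alarms: int

    @property
    def mean_onset_error_s(self) -> float:
        return float(np.mean(self.onset_errors_s)) if self.n_matched else float("nan")

    @property
    def mean_offset_error_s(self) -> float:
        return float(np.mean(self.offset_errors_s)) if self.n_matched else float("nan")

    @property
    def mean_abs_onset_error_s(self) -> float:
        return float(np.mean(np.abs(self.onset_errors_s))) if self.n_matched else float("nan")

    @property
    def mean_abs_offset_error_s(self) -> float:
        return float(np.mean(np.abs(self.offset_errors_s))) if self.n_matched else float("nan")

    @property
    def mean_onset_error_rel_pct(self) -> float:
        return float(np.mean(self.onset_errors_rel_pct)) if self.n_matched else float("nan")

    @property
    def mean_offset_error_rel_pct(self) -> float:
        return float(np.mean(self.offset_errors_rel_pct)) if self.n_matched else float("nan")


def score_events(
    detected: EventList, reference: EventList, max_lag_s: float | None = None
) -> TimingErrorReport:
    """Match detected to reference events and report signed timing errors.

    Greedy nearest-neighbour matching on onsets within ``max_lag_s``
    (default: half the median reference onset-to-onset interval), one-to-one,
    closest pairs first.
    """
    if len(reference) == 0:
        raise ValueError("reference event list is empty")

    ref_on = reference.onsets
    det_on = detected.onsets
    if len(ref_on) >= 2:
        cycle_durs = np.diff(ref_on)
        median_cycle = float(np.median(cycle_durs))
    else:
        cycle_durs = np.array([])
        median_cycle = reference[0].duration * 2.0
    if max_lag_s is None:
        max_lag_s = median_cycle / 2.0

    pairs = [
        (abs(d - r), i, j)
        for i, d in enumerate(det_on)
        for j, r in enumerate(ref_on)
        if abs(d - r) <= max_lag_s
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_ref: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_det or j in used_ref:
            continue
        used_det.add(i)
        used_ref.add(j)
        matches.append((i, j))
    matches.sort(key=lambda m: m[1])

    onset_err, offset_err, onset_rel, offset_rel = [], [], [], []
    for i, j in matches:
        d_on = detected[i].onset - reference[j].onset
        d_off = detected[i].offset - reference[j].offset
        dur = float(cycle_durs[j]) if j < len(cycle_durs) else median_cycle
        onset_err.append(d_on)
        offset_err.append(d_off)
        onset_rel.append(100.0 * d_on / dur)
        offset_rel.append(100.0 * d_off / dur)

    return TimingErrorReport(
        onset_errors_s=np.array(onset_err),
        offset_errors_s=np.array(offset_err),
        onset_errors_rel_pct=np.array(onset_rel),
        offset_errors_rel_pct=np.array(offset_rel),
        n_matched=len(matches),
        n_missed=len(ref_on) - len(matches),
        n_false_alarms=len(det_on) - len(matches),
    )


def reference_events_from_trajectory(
    traj: ReferenceSeries, prominence: float = 10.0
) -> EventList:
    """Reference grasp/release instants from a wrist-marker vertical
    trajectory.

    During pick-and-place, the wrist is lowest exactly when the object is
    grasped or released, so local minima of the vertical coordinate
    (deeper than ``prominence``, in the trajectory's units) are the event
    instants.  Consecutive minima pair into (grasp, release) events:
    minima 0-1 form the first event, 2-3 the second, and so on; a trailing
    unpaired minimum is dropped.
    """
    y = np.asarray(traj.values, dtype=float)
    if len(y) < 5:
        raise ValueError("trajectory too short")
    minima, _ = sps.find_peaks(-y, prominence=prominence)
    if len(minima) < 2:
        logger.warning("fewer than 2 minima found; returning empty event list")
        return EventList(events=[], source="reference")
    events = [
        GraspEvent(
            onset=float(traj.timestamps[minima[k]]),
            offset=float(traj.timestamps[minima[k + 1]]),
            peak_value=float(np.max(y[minima[k] : minima[k + 1] + 1])),
        )
        for k in range(0, len(minima) - 1, 2)
    ]
    return EventList(events=events, source="reference")
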
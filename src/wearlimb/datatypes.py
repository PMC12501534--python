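"""Domain containers shared across the package.

Everything is a plain dataclass over numpy arrays, validated on
construction.  Angles are degrees, times are seconds, FSR readings are the
raw unitless sensor output (the hardware's sensing range maps to roughly
0.2–20 N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import quaternions as quat

__all__ = [
    "Recording",
    "ReferenceSeries",
    "GraspEvent",
    "EventList",
    "JointAngleSeries",
    "AngularVelocitySeries",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


def _check_timestamps(t: np.ndarray) -> None:
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(t)):
        raise ValueError("timestamps must be finite")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")


@dataclass
class Recording:
    """Synchronized multi-sensor time series from one armband/trunk session.

    Three orientation streams (trunk, upper arm, forearm) as scalar-first
    unit quaternions plus two 8-channel FSR arrays (upper and lower
    armband), nominally sampled at 18 Hz.  Quaternions are renormalized on
    construction; FSR values must be finite and non-negative.
    """

    timestamps: np.ndarray
    trunk_quat: np.ndarray
    upperarm_quat: np.ndarray
    forearm_quat: np.ndarray
    fsr_upper: np.ndarray
    fsr_lower: np.ndarray
    rate_hz: float = 18.0

    def __post_init__(self) -> None:
        self.timestamps = _as_1d(self.timestamps, "timestamps")
        _check_timestamps(self.timestamps)
        n = len(self.timestamps)
        for name in ("trunk_quat", "upperarm_quat", "forearm_quat"):
            q = np.asarray(getattr(self, name), dtype=float)
            if q.shape != (n, 4):
                raise ValueError(f"{name} must have shape ({n}, 4), got {q.shape}")
            if not np.all(np.isfinite(q)):
                raise ValueError(f"{name} contains non-finite values")
            norms = np.linalg.norm(q, axis=1)
            if np.any(norms < 1e-6):
                raise ValueError(f"{name} contains zero quaternions")
            setattr(self, name, quat.normalize(q))
        for name in ("fsr_upper", "fsr_lower"):
            f = np.asarray(getattr(self, name), dtype=float)
            if f.shape != (n, 8):
                raise ValueError(f"{name} must have shape ({n}, 8), got {f.shape}")
            if not np.all(np.isfinite(f)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(f < 0):
                raise ValueError(f"{name} contains negative values")
            setattr(self, name, f)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class ReferenceSeries:
    """A single reference channel (joint angle in degrees or marker
    coordinate in millimetres), e.g. from optical motion capture at 100 Hz."""

    timestamps: np.ndarray
    values: np.ndarray
    rate_hz: float = 100.0
    label: str = ""

    def __post_init__(self) -> None:
        self.timestamps = _as_1d(self.timestamps, "timestamps")
        self.values = _as_1d(self.values, "values")
        _check_timestamps(self.timestamps)
        if len(self.values) != len(self.timestamps):
            raise ValueError("values and timestamps must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class GraspEvent:
    """One grasp interval: hand loaded from ``onset`` to ``offset`` seconds."""

    onset: float
    offset: float
    peak_value: float = float("nan")

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError(f"onset ({self.onset}) must precede offset ({self.offset})")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EventList:
    """Ordered, non-overlapping grasp events from one detector run."""

    events: list[GraspEvent] = field(default_factory=list)
    source: str = "fsr"  # {"fsr", "reference"}

    def __post_init__(self) -> None:
        if self.source not in ("fsr", "reference"):
            raise ValueError(f"unknown event source {self.source!r}")
        self.events = sorted(self.events, key=lambda e: e.onset)
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset < prev.offset:
                raise ValueError(
                    f"overlapping events: ({prev.onset}, {prev.offset}) and "
                    f"({nxt.onset}, {nxt.offset})"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.events])


@dataclass
class JointAngleSeries:
    """Per-joint angle traces in degrees.

    ``flexion`` is positive in flexion for both joints; ``abduction`` is
    positive in abduction and carried only for the shoulder (``None`` for
    the elbow).  ``gimbal_flags`` marks samples where the YZX extraction
    was degenerate (|theta_z| ~ 90°).
    """

    timestamps: np.ndarray
    flexion: np.ndarray
    joint: str  # {"shoulder", "elbow"}
    abduction: Optional[np.ndarray] = None
    gimbal_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = _as_1d(self.timestamps, "timestamps")
        self.flexion = _as_1d(self.flexion, "flexion")
        _check_timestamps(self.timestamps)
        if self.joint not in ("shoulder", "elbow"):
            raise ValueError(f"unknown joint {self.joint!r}")
        n = len(self.timestamps)
        if len(self.flexion) != n:
            raise ValueError("flexion length mismatch")
        if not np.all(np.isfinite(self.flexion)):
            raise ValueError("flexion must be finite")
        if self.abduction is not None:
            self.abduction = _as_1d(self.abduction, "abduction")
            if len(self.abduction) != n:
                raise ValueError("abduction length mismatch")
            if not np.all(np.isfinite(self.abduction)):
                raise ValueError("abduction must be finite")
        if self.gimbal_flags is None:
            self.gimbal_flags = np.zeros(n, dtype=bool)
        else:
            self.gimbal_flags = np.asarray(self.gimbal_flags, dtype=bool)
            if len(self.gimbal_flags) != n:
                raise ValueError("gimbal_flags length mismatch")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class AngularVelocitySeries:
    """Body-frame angular velocity about the sensor's internal y axis,
    deg/s, from forward differences — one sample per inter-sample step
    (length n-1), timestamped at the left sample of each step."""

    timestamps: np.ndarray
    omega_y: np.ndarray
    segment: str  # {"upperarm", "forearm"}

    def __post_init__(self) -> None:
        self.timestamps = _as_1d(self.timestamps, "timestamps")
        self.omega_y = _as_1d(self.omega_y, "omega_y")
        if self.segment not in ("upperarm", "forearm"):
            raise ValueError(f"unknown segment {self.segment!r}")
        if len(self.omega_y) != len(self.timestamps):
            raise ValueError("omega_y length mismatch")
        if not np.all(np.isfinite(self.omega_y)):
            raise ValueError("omega_y must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)
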
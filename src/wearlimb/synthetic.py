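"""Synthetic motion and sensor simulator — the package's test bed.

Generates ground-truth shoulder/elbow angle trajectories for a battery of
upper-limb tasks, composes the corresponding trunk/upper-arm/forearm
sensor quaternion streams (with configurable orientation noise, shared
heading drift and soft-tissue-like perturbation) and forearm FSR burst
signals time-locked to grasp intervals.

Tasks
-----
T1  shoulder flexion 0→90° in the sagittal plane
T2  shoulder flexion in a 45° diagonal plane (stylized here as
    simultaneous flexion→amplitude and abduction→amplitude/2)
T3  shoulder abduction 0→90°
T4  elbow flexion 0→90°
T5  sequenced elbow-then-shoulder flexion with holds (elbow 0→90, then
    shoulder 0→90 holding the elbow, then elbow back, then shoulder back)
T6  shoulder flexion 0→160° with the trunk flexed 40° forward
T7 / worker_cycle
    repetitive pick–carry–place work cycles with a grasp-interval
    schedule; cycle durations are jittered with a configurable CV
    (default 5 %, the consistency regime of repetitive packing work)

Movement profiles are raised-cosine ramp–hold–return excursions (C¹
smooth, extrema analytically known), one repetition per ``period_s``
(default 4 s — movements are at a self-selected comfortable tempo, so the
tempo is a package default, not a measured value).  Translation during
carrying is not modelled: the sensors are orientation-only, so only the
timing structure of the carry phase matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import quaternions as quat
from .datatypes import EventList, GraspEvent, JointAngleSeries, Recording

__all__ = [
    "MotionSpec",
    "NoiseSpec",
    "GroundTruth",
    "generate_ground_truth",
    "compose_sensors",
    "compose_fsr",
    "simulate_recording",
    "TASKS",
]

TASKS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "worker_cycle")


@dataclass
class MotionSpec:
    """One simulated task.

    amplitude_deg defaults by task (90° for T1–T5, 160° for T6, 60° for
    the worker cycle); repetitions default to 8 (one recorded set);
    trunk_flexion_deg defaults to 40° for T6 and 0 otherwise;
    duration_cv jitters worker-cycle durations (fractional CV).
    """

    task: str = "T1"
    amplitude_deg: Optional[float] = None
    repetitions: int = 8
    period_s: float = 4.0
    hold_s: Optional[float] = None
    trunk_flexion_deg: Optional[float] = None
    duration_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.amplitude_deg is None:
            self.amplitude_deg = 160.0 if self.task == "T6" else (
                60.0 if self.task in ("T7", "worker_cycle") else 90.0
            )
        if not 0.0 < self.amplitude_deg < 180.0:
            raise ValueError("amplitude_deg must be in (0, 180)")
        if self.trunk_flexion_deg is None:
            self.trunk_flexion_deg = 40.0 if self.task == "T6" else 0.0
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")
        if self.duration_cv < 0:
            raise ValueError("duration_cv must be >= 0")


@dataclass
class NoiseSpec:
    """Sensor imperfection model.

    orientation_sigma_deg : per-axis SD of i.i.d. small-angle
        multiplicative quaternion noise on each sensor sample.
    fsr_sigma : additive Gaussian FSR noise, as a fraction of the burst
        amplitude.
    drift_rate_deg_per_min : slow shared heading drift about the vertical
        axis, applied to ALL sensors (cancels in relative joint angles).
    soft_tissue_amp_deg / soft_tissue_freq_hz : per-sensor low-frequency
        sinusoidal perturbation approximating soft-tissue artifact
        (amplitude 0 disables it).
    """

    orientation_sigma_deg: float = 0.0
    fsr_sigma: float = 0.0
    drift_rate_deg_per_min: float = 0.0
    soft_tissue_amp_deg: float = 0.0
    soft_tissue_freq_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("orientation_sigma_deg", "fsr_sigma", "drift_rate_deg_per_min",
                     "soft_tissue_amp_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Noise-free joint-angle trajectories plus the grasp schedule (T7)."""

    timestamps: np.ndarray
    shoulder: JointAngleSeries
    elbow: JointAngleSeries
    trunk_flexion_deg: np.ndarray
    schedule: Optional[EventList]
    rate_hz: float


def _ramp_hold(phase: np.ndarray, up: float, hold: float, down: float) -> np.ndarray:
    """Raised-cosine ramp 0→1 over [0, up], hold 1 to up+hold, raised-cosine
    return to 0 by up+hold+down, 0 afterwards.  ``phase`` in [0, 1)."""
    y = np.zeros_like(phase)
    m = phase < up
    y[m] = 0.5 * (1.0 - np.cos(np.pi * phase[m] / up))
    m = (phase >= up) & (phase < up + hold)
    y[m] = 1.0
    m = (phase >= up + hold) & (phase < up + hold + down)
    y[m] = 0.5 * (1.0 + np.cos(np.pi * (phase[m] - up - hold) / down))
    return y


def _bump(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """sin² bump: 0 at t0 and t1, 1 at the midpoint, 0 outside."""
    y = np.zeros_like(t)
    m = (t >= t0) & (t <= t1)
    y[m] = np.sin(np.pi * (t[m] - t0) / (t1 - t0)) ** 2
    return y


def _worker_schedule(spec: MotionSpec) -> tuple[np.ndarray, float, EventList]:
    """Jittered cycle start times, total duration and the grasp schedule."""
    rng = np.random.default_rng(spec.seed)
    durs = spec.period_s * (1.0 + spec.duration_cv * rng.standard_normal(spec.repetitions))
    durs = np.clip(durs, 0.3 * spec.period_s, None)
    starts = np.concatenate([[0.0], np.cumsum(durs)])[:-1]
    lead = 0.1 * spec.period_s  # fixed grasp lead-in, not jittered
    events = [
        GraspEvent(onset=float(s + lead), offset=float(s + lead + 0.45 * d))
        for s, d in zip(starts, durs)
    ]
    total = float(starts[-1] + durs[-1] + lead + 2.0)
    return starts, total, EventList(events=events, source="reference")


def generate_ground_truth(spec: MotionSpec, rate_hz: float = 18.0) -> GroundTruth:
    """Sample the task's analytic angle trajectories at ``rate_hz``.

    The trajectory is a deterministic function of the spec (worker-cycle
    duration jitter is drawn from ``spec.seed``), so the same spec sampled
    at 18 and 100 Hz describes the same underlying motion.
    """
    p = spec.period_s
    if spec.task in ("T7", "worker_cycle"):
        starts, total, schedule = _worker_schedule(spec)
        n = int(np.floor(total * rate_hz)) + 1
        t = np.arange(n) / rate_hz
        sh = np.zeros(n)
        el = np.zeros(n)
        for e in schedule:
            sh += spec.amplitude_deg * _bump(t, e.onset, e.offset)
            el += 0.75 * spec.amplitude_deg * _bump(t, e.onset, e.offset)
        abd = np.zeros(n)
        trunk = np.zeros(n)
    else:
        schedule = None
        total = spec.repetitions * p
        n = int(np.floor(total * rate_hz)) + 1
        t = np.arange(n) / rate_hz
        phase = (t % p) / p
        phase[t >= total] = 0.0  # final grid point closes the last repetition
        A = spec.amplitude_deg
        sh = np.zeros(n)
        el = np.zeros(n)
        abd = np.zeros(n)
        if spec.task == "T1":
            sh = A * _ramp_hold(phase, 0.3, 0.2, 0.3)
        elif spec.task == "T2":
            s = _ramp_hold(phase, 0.3, 0.2, 0.3)
            sh = A * s
            abd = 0.5 * A * s
        elif spec.task == "T3":
            abd = A * _ramp_hold(phase, 0.3, 0.2, 0.3)
        elif spec.task == "T4":
            el = A * _ramp_hold(phase, 0.3, 0.2, 0.3)
        elif spec.task == "T5":
            # elbow up | shoulder up | elbow down | shoulder down | rest
            el = A * _ramp_hold(phase, 0.18, 0.22, 0.18)
            sh = A * _ramp_hold(np.clip(phase - 0.19, 0.0, 1.0), 0.18, 0.41, 0.18)
        elif spec.task == "T6":
            sh = A * _ramp_hold(phase, 0.3, 0.2, 0.3)
        trunk = np.full(n, float(spec.trunk_flexion_deg))

    shoulder = JointAngleSeries(timestamps=t, flexion=sh, abduction=abd, joint="shoulder")
    elbow = JointAngleSeries(timestamps=t, flexion=el, joint="elbow")
    return GroundTruth(
        timestamps=t, shoulder=shoulder, elbow=elbow,
        trunk_flexion_deg=trunk, schedule=schedule, rate_hz=rate_hz,
    )


def _noise_quats(rng: np.random.Generator, n: int, sigma_deg: float) -> np.ndarray:
    if sigma_deg == 0.0:
        q = np.zeros((n, 4))
        q[:, 0] = 1.0
        return q
    rotvec = np.deg2rad(sigma_deg) * rng.standard_normal((n, 3))
    angle = np.linalg.norm(rotvec, axis=1)
    q = np.zeros((n, 4))
    q[:, 0] = np.cos(angle / 2)
    small = angle < 1e-12
    scale = np.where(small, 0.5, np.sin(angle / 2) / np.where(small, 1.0, angle))
    q[:, 1:] = rotvec * scale[:, None]
    return quat.normalize(q)


def compose_sensors(truth: GroundTruth, noise: NoiseSpec | None = None) -> Recording:
    """Compose the three sensor quaternion streams (and FSR arrays) that a
    recording of ``truth`` would contain.

    The joint rotations are built in the same intrinsic YZX convention the
    kinematics module inverts: shoulder rotation = YZX(-flexion,
    +abduction, 0), elbow rotation = YZX(+flexion, 0, 0), so noise-free
    composition→decomposition is exact.  Upper arm = trunk ⊗ shoulder;
    forearm = upper arm ⊗ elbow.  Shared heading drift left-multiplies all
    three streams (and therefore cancels in the joint angles); per-sensor
    orientation noise right-multiplies each stream.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    t = truth.timestamps
    n = len(t)

    q_trunk = quat.from_euler_yzx(-truth.trunk_flexion_deg, 0.0, 0.0)
    abd = truth.shoulder.abduction
    q_sh = quat.from_euler_yzx(-truth.shoulder.flexion, abd, 0.0)
    q_el = quat.from_euler_yzx(truth.elbow.flexion, 0.0, 0.0)

    q_ua = quat.multiply(q_trunk, q_sh)
    q_fa = quat.multiply(q_ua, q_el)

    if noise.drift_rate_deg_per_min > 0.0:
        drift_deg = noise.drift_rate_deg_per_min * t / 60.0
        g = quat.from_euler_yzx(0.0, 0.0, drift_deg)  # about the vertical (x) axis
        q_trunk = quat.multiply(g, q_trunk)
        q_ua = quat.multiply(g, q_ua)
        q_fa = quat.multiply(g, q_fa)

    streams = [q_trunk, q_ua, q_fa]
    if noise.soft_tissue_amp_deg > 0.0:
        for i, q in enumerate(streams):
            phase = rng.uniform(0, 2 * np.pi)
            wob = noise.soft_tissue_amp_deg * np.sin(
                2 * np.pi * noise.soft_tissue_freq_hz * t + phase
            )
            streams[i] = quat.multiply(q, quat.from_euler_yzx(wob, 0.0, 0.0))
    if noise.orientation_sigma_deg > 0.0:
        streams = [
            quat.multiply(q, _noise_quats(rng, n, noise.orientation_sigma_deg))
            for q in streams
        ]

    schedule = truth.schedule
    fsr_lower = compose_fsr(schedule, noise, t, amplitude=1.0, rng=rng)
    fsr_upper = compose_fsr(schedule, noise, t, amplitude=0.5, rng=rng)
    return Recording(
        timestamps=t,
        trunk_quat=streams[0],
        upperarm_quat=streams[1],
        forearm_quat=streams[2],
        fsr_upper=fsr_upper,
        fsr_lower=fsr_lower,
        rate_hz=truth.rate_hz,
    )


def compose_fsr(
    schedule: Optional[EventList],
    noise: NoiseSpec | None,
    timestamps: np.ndarray,
    baseline: float = 0.1,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """n×8 FSR array: baseline plus one sin² burst per grasp interval.

    Each channel gets an amplitude jitter (uniform ±20 %); the averaged
    signal's delimiting minima fall at the interval edges by construction.
    Additive Gaussian noise with SD = ``fsr_sigma``·amplitude; readings
    clipped at 0 (the sensor cannot report negative force).
    """
    noise = noise or NoiseSpec()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    t = np.asarray(timestamps, dtype=float)
    n = len(t)
    out = np.full((n, 8), baseline)
    if schedule is not None and len(schedule):
        onsets = schedule.onsets
        offsets = schedule.offsets
        if np.any(onsets[1:] < offsets[:-1]):
            raise ValueError("overlapping grasp schedule")
        amps = amplitude * (1.0 + rng.uniform(-0.2, 0.2, size=8))
        for on, off in zip(onsets, offsets):
            burst = _bump(t, on, off)
            out += burst[:, None] * amps[None, :]
    if noise.fsr_sigma > 0.0:
        out = out + noise.fsr_sigma * amplitude * rng.standard_normal((n, 8))
    return np.clip(out, 0.0, None)


def simulate_recording(
    spec: MotionSpec, noise: NoiseSpec | None = None, rate_hz: float = 18.0
) -> tuple[Recording, GroundTruth]:
    """Generate ground truth and the corresponding sensor Recording."""
    truth = generate_ground_truth(spec, rate_hz=rate_hz)
    return compose_sensors(truth, noise), truth
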
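"""Shoulder and elbow joint angles from three sensor orientation streams.

The relative rotation between two adjacent segments' sensors is the joint
rotation: the proximal sensor quaternion is conjugated and multiplied by
the distal one, then decomposed with the intrinsic YZX Euler sequence.
With the sensors' internal frames (x up, y along the frontal axis, z along
the sagittal axis), theta_y is flexion/extension, theta_z ab/adduction and
theta_x internal/external rotation.

Sign conventions (right arm): shoulder flexion = -theta_y (the shoulder
sensor's y angle runs opposite to anatomical flexion), shoulder abduction
= +theta_z; elbow flexion = +theta_y (upper-arm and forearm sensor axes
are mounted aligned, so no negation).

No sensor-to-segment calibration is applied by default — the system is
designed to work from an alignment check in a neutral posture alone.  An
optional static offset (mean over a user-marked still window) can be
subtracted via ``npose_offset``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import quaternions as quat
from .datatypes import AngularVelocitySeries, JointAngleSeries

__all__ = ["shoulder_angles", "elbow_angles", "flexion_velocity", "npose_offset"]


def _relative_euler(proximal: np.ndarray, distal: np.ndarray):
    proximal = np.asarray(proximal, dtype=float)
    distal = np.asarray(distal, dtype=float)
    if proximal.shape != distal.shape:
        raise ValueError(
            f"stream length mismatch: proximal {proximal.shape} vs distal {distal.shape}"
        )
    q_joint = quat.multiply(quat.conjugate(proximal), distal)
    return quat.to_euler_yzx(q_joint)


def shoulder_angles(
    trunk: np.ndarray,
    upperarm: np.ndarray,
    timestamps: np.ndarray,
    offset_deg: Optional[tuple[float, float]] = None,
) -> JointAngleSeries:
    """Shoulder flexion/extension and ab/adduction from trunk and upper-arm
    sensor quaternions.

    Per sample ``q_shoulder = conj(q_trunk) ⊗ q_upperarm``; YZX extraction;
    flexion = -theta_y, abduction = +theta_z (right arm).  Gimbal-degenerate
    samples (|theta_z| ~ 90°) are flagged, never dropped.

    Parameters
    ----------
    offset_deg : optional (flexion, abduction) static offset subtracted
        from the output, e.g. from :func:`npose_offset`.  Off by default.
    """
    angles, gimbal = _relative_euler(trunk, upperarm)
    flexion = -angles[..., 0]
    abduction = angles[..., 1]
    if offset_deg is not None:
        flexion = flexion - offset_deg[0]
        abduction = abduction - offset_deg[1]
    return JointAngleSeries(
        timestamps=np.asarray(timestamps, dtype=float),
        flexion=flexion,
        abduction=abduction,
        joint="shoulder",
        gimbal_flags=gimbal,
    )


def elbow_angles(
    upperarm: np.ndarray,
    forearm: np.ndarray,
    timestamps: np.ndarray,
    offset_deg: Optional[float] = None,
) -> JointAngleSeries:
    """Elbow flexion/extension from upper-arm and forearm sensor quaternions.

    ``q_elbow = conj(q_upperarm) ⊗ q_forearm``; YZX extraction; flexion =
    +theta_y (both sensors' axes are mounted with the same orientation, so
    no negation is needed).  The elbow carries no abduction channel.
    """
    angles, gimbal = _relative_euler(upperarm, forearm)
    flexion = angles[..., 0]
    if offset_deg is not None:
        flexion = flexion - offset_deg
    return JointAngleSeries(
        timestamps=np.asarray(timestamps, dtype=float),
        flexion=flexion,
        abduction=None,
        joint="elbow",
        gimbal_flags=gimbal,
    )


def npose_offset(series: JointAngleSeries, t_start: float, t_end: float):
    """Mean angle over a still window [t_start, t_end] — a static N-pose
    offset usable with the ``offset_deg`` argument of the angle functions."""
    mask = (series.timestamps >= t_start) & (series.timestamps <= t_end)
    if not np.any(mask):
        raise ValueError("still window contains no samples")
    flex = float(np.mean(series.flexion[mask]))
    if series.abduction is not None:
        return flex, float(np.mean(series.abduction[mask]))
    return flex


def flexion_velocity(
    quats: np.ndarray, timestamps: np.ndarray, segment: str = "upperarm"
) -> AngularVelocitySeries:
    """Body-frame angular velocity about the sensor's internal y axis, deg/s.

    Forward difference of the quaternion log-map: for consecutive samples
    ``omega = 2·log(conj(q_t) ⊗ q_{t+1}) / dt`` (axis·angle over dt), whose
    y component is the flexion velocity of the joint proximal to the
    segment.  Exact for constant-rate single-axis motion; length n-1,
    timestamped at the left sample.
    """
    quats = np.asarray(quats, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if quats.ndim != 2 or quats.shape[1] != 4:
        raise ValueError(f"quats must be (n, 4), got {quats.shape}")
    if len(quats) != len(timestamps):
        raise ValueError("quats/timestamps length mismatch")
    if len(quats) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(timestamps)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dq = quat.multiply(quat.conjugate(quats[:-1]), quats[1:])
    rotvec = quat.rotvec_log(dq)  # radians, body frame
    omega_y = np.rad2deg(rotvec[:, 1]) / dt
    return AngularVelocitySeries(
        timestamps=timestamps[:-1], omega_y=omega_y, segment=segment
    )
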
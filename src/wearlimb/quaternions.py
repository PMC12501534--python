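"""Convention-pinned quaternion algebra and YZX Euler extraction.

Conventions (fixed for the whole package):

* **Hamilton** quaternions, right-handed, **scalar-first** ``(w, x, y, z)``.
* ``q`` and ``-q`` represent the same rotation; every consumer treats them
  as equal.
* Euler extraction uses the **intrinsic Y-Z-X** sequence (successive
  rotations about the body-fixed y, then z, then x axes), the decomposition
  used to read joint angles out of a relative sensor rotation: y = flexion/
  extension, z = ab/adduction, x = internal/external rotation.
* Angles are reported in degrees; radians appear only internally.

All functions are vectorised over a leading axis: a "quaternion array" is
any float array of shape ``(..., 4)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "conjugate",
    "multiply",
    "from_euler_yzx",
    "to_euler_yzx",
    "to_rotation_matrix",
    "rotvec_log",
    "UNIT_TOL",
    "GIMBAL_TOL_DEG",
]

#: tolerance on the unit-norm invariant for inputs
UNIT_TOL = 1e-6
#: |theta_z| closer than this (degrees) to 90 is flagged gimbal-degenerate
GIMBAL_TOL_DEG = 0.01


def _check_unit(q: np.ndarray, tol: float = 1e-3) -> None:
    norms = np.linalg.norm(q, axis=-1)
    if not np.all(np.abs(norms - 1.0) < tol):
        worst = float(np.max(np.abs(norms - 1.0)))
        raise ValueError(f"non-unit quaternion input (max |norm-1| = {worst:.3g})")


def normalize(q: np.ndarray) -> np.ndarray:
    """Rescale to unit norm. Raises on (near-)zero quaternions."""
    q = np.asarray(q, dtype=float)
    norms = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("cannot normalize a zero quaternion")
    return q / norms


def conjugate(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate ``(w, -x, -y, -z)`` — the inverse rotation for unit q."""
    q = np.asarray(q, dtype=float)
    _check_unit(q)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``: the rotation b expressed after a.

    Result is renormalized to keep the unit invariant tight under long
    compositions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_unit(a)
    _check_unit(b)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    out = np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )
    return normalize(out)


def to_rotation_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (``(..., 3, 3)``) of a unit quaternion."""
    q = normalize(np.asarray(q, dtype=float))
    w, x, y, z = (q[..., i] for i in range(4))
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def _axis_quat(angle_rad: np.ndarray, axis: int) -> np.ndarray:
    angle_rad = np.asarray(angle_rad, dtype=float)
    half = angle_rad / 2.0
    q = np.zeros(angle_rad.shape + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1 + axis] = np.sin(half)
    return q


def from_euler_yzx(theta_y_deg, theta_z_deg, theta_x_deg) -> np.ndarray:
    """Compose a quaternion from intrinsic Y-Z-X angles in degrees.

    ``q = q_y(theta_y) ⊗ q_z(theta_z) ⊗ q_x(theta_x)`` — the exact inverse
    of :func:`to_euler_yzx` away from gimbal lock.
    """
    ty = np.deg2rad(np.asarray(theta_y_deg, dtype=float))
    tz = np.deg2rad(np.asarray(theta_z_deg, dtype=float))
    tx = np.deg2rad(np.asarray(theta_x_deg, dtype=float))
    ty, tz, tx = np.broadcast_arrays(ty, tz, tx)
    return multiply(multiply(_axis_quat(ty, 1), _axis_quat(tz, 2)), _axis_quat(tx, 0))


def to_euler_yzx(q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Intrinsic Y-Z-X Euler angles of a unit quaternion, in degrees.

    Returns ``(angles, gimbal)`` where ``angles[..., 0:3]`` are
    ``(theta_y, theta_z, theta_x)`` with ``theta_y, theta_x`` in
    (-180, 180] and ``theta_z`` in [-90, 90], and ``gimbal`` is a boolean
    mask flagging samples with |theta_z| within ``GIMBAL_TOL_DEG`` of 90°.
    At gimbal lock only the sum/difference of the outer angles is defined;
    by convention ``theta_x := 0`` there and ``theta_y`` absorbs the rest —
    degenerate samples are flagged, never raised, so a long recording does
    not abort on one bad sample.

    Derivation: for R = Ry(a)·Rz(b)·Rx(c),
    ``R[1,0] = sin b``, ``R[2,0] = -sin a cos b``, ``R[0,0] = cos a cos b``,
    ``R[1,2] = -cos b sin c``, ``R[1,1] = cos b cos c``.
    """
    q = np.asarray(q, dtype=float)
    _check_unit(q)
    m = to_rotation_matrix(q)

    s_z = np.clip(m[..., 1, 0], -1.0, 1.0)
    theta_z = np.arcsin(s_z)
    gimbal = np.abs(np.abs(np.rad2deg(theta_z)) - 90.0) < GIMBAL_TOL_DEG

    theta_y = np.arctan2(-m[..., 2, 0], m[..., 0, 0])
    theta_x = np.arctan2(-m[..., 1, 2], m[..., 1, 1])

    if np.any(gimbal):
        # cos b -> 0: recover theta_y from the surviving entries with theta_x := 0
        ty_lock = np.arctan2(m[..., 0, 2], m[..., 2, 2])
        theta_y = np.where(gimbal, ty_lock, theta_y)
        theta_x = np.where(gimbal, 0.0, theta_x)

    angles = np.rad2deg(np.stack([theta_y, theta_z, theta_x], axis=-1))
    return angles, gimbal


def rotvec_log(q: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, radians) of a unit quaternion: 2·log(q).

    The sign ambiguity is resolved toward the short arc (angle <= pi).
    Used for body-frame finite-difference angular velocity.
    """
    q = normalize(np.asarray(q, dtype=float))
    # pick the hemisphere with w >= 0 so the angle is the short one
    q = np.where(q[..., :1] < 0.0, -q, q)
    w = np.clip(q[..., 0], -1.0, 1.0)
    vec = q[..., 1:]
    sin_half = np.linalg.norm(vec, axis=-1)
    angle = 2.0 * np.arctan2(sin_half, w)
    # sinc-safe scale: angle / sin(angle/2), -> 2 as angle -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(sin_half > 1e-12, angle / np.where(sin_half > 1e-12, sin_half, 1.0), 2.0)
    return vec * scale[..., None]
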
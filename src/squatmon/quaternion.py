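"""Unit-quaternion helpers for attitude representation.

Quaternions are stored as ``(w, x, y, z)`` numpy arrays and represent the
rotation taking sensor-frame vectors into the Earth frame (ENU, +z up):
``v_earth = q ⊗ (0, v_sensor) ⊗ q*``.

Only the handful of operations the attitude pipeline needs are provided;
array-valued variants operate on ``(n, 4)`` stacks where noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qmul",
    "qconj",
    "qnormalize",
    "qrotate",
    "qrotate_inv",
    "to_matrix",
    "from_matrix",
    "from_axis_angle",
    "identity",
]


def identity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b (both (4,) or broadcastable (n, 4))."""
    aw, ax, ay, az = np.moveaxis(np.asarray(a, dtype=float), -1, 0)
    bw, bx, by, bz = np.moveaxis(np.asarray(b, dtype=float), -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    return q / n


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v from the sensor frame to the Earth frame."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # Rodrigues form of q v q*
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def qrotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v from the Earth frame back to the sensor frame."""
    return qrotate(qconj(np.asarray(q, dtype=float)), v)


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with v_earth = R v_sensor; supports (n, 4) stacks."""
    q = qnormalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    R = np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )
    return R


def from_matrix(R: np.ndarray) -> np.ndarray:
    """Quaternion from a proper rotation matrix (Shepperd's method, (…,3,3))."""
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    w = 0.5 * np.sqrt(np.clip(1.0 + R[..., 0, 0] + R[..., 1, 1] + R[..., 2, 2], 0.0, None))
    # avoid division blow-up near w=0 by falling back to the dominant axis
    q = np.empty(R.shape[:-2] + (4,))
    safe = w > 1e-6
    q[safe, 0] = w[safe]
    q[safe, 1] = (R[safe, 2, 1] - R[safe, 1, 2]) / (4 * w[safe])
    q[safe, 2] = (R[safe, 0, 2] - R[safe, 2, 0]) / (4 * w[safe])
    q[safe, 3] = (R[safe, 1, 0] - R[safe, 0, 1]) / (4 * w[safe])
    if np.any(~safe):
        for i in np.flatnonzero(~safe):
            M = R[i]
            k = int(np.argmax(np.diag(M)))
            j, l = (k + 1) % 3, (k + 2) % 3
            s = np.sqrt(max(M[k, k] - M[j, j] - M[l, l] + 1.0, 0.0))
            qi = np.empty(4)
            qi[1 + k] = 0.5 * s
            s = 0.5 / s
            qi[0] = (M[l, j] - M[j, l]) * s
            qi[1 + j] = (M[j, k] + M[k, j]) * s
            qi[1 + l] = (M[l, k] + M[k, l]) * s
            q[i] = qi
    q = qnormalize(q)
    # canonical sign: non-negative scalar part
    q = np.where(q[..., :1] < 0, -q, q)
    return q[0] if single else q


def from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[np.cos(angle / 2.0)], np.sin(angle / 2.0) * axis])


def angle_between(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Geodesic angle (rad) between two attitudes; supports stacks."""
    d = np.abs(np.sum(qnormalize(qa) * qnormalize(qb), axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))
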
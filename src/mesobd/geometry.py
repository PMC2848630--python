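"""Quaternion and small-vector helpers used throughout the simulator.

All rotations are active, right-handed, and represented as unit quaternions
``(w, x, y, z)``.  Functions accept either a single quaternion of shape
``(4,)`` or a batch of shape ``(n, 4)``; vectors are ``(3,)`` or ``(n, 3)``.
The hot paths of the engine call these instead of constructing
``scipy.spatial.transform.Rotation`` objects, which carry per-call overhead;
the scipy implementation is used as an independent oracle in the test suite.
"""

from __future__ import annotations

import numpy as np

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


def normalize(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit length (last axis)."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0.0):
        raise ValueError("cannot normalise a zero vector")
    return v / n


def qmult(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1*q2 (apply q2 first, then q1)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    w2, x2, y2, z2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    out = np.empty(np.broadcast(q1, q2).shape)
    out[..., 0] = w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2
    out[..., 1] = w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2
    out[..., 2] = w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2
    out[..., 3] = w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2
    return out


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q``."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2w(u x v) + 2u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = normalize(np.asarray(axis, dtype=float))
    half = 0.5 * float(angle)
    return np.array([np.cos(half), *(np.sin(half) * axis)])


def y_rotation_quat(angle) -> np.ndarray:
    """Rotation(s) about the +y axis by ``angle`` (scalar or array)."""
    angle = np.asarray(angle, dtype=float)
    half = 0.5 * angle
    w = np.cos(half)
    y = np.sin(half)
    z = np.zeros_like(w)
    return np.stack([w, z, y, z], axis=-1)


def random_quaternion(normals: np.ndarray) -> np.ndarray:
    """Uniform random rotation(s) built from 4 standard normals (per row)."""
    normals = np.asarray(normals, dtype=float)
    n = np.linalg.norm(normals, axis=-1, keepdims=True)
    # A zero draw has probability zero; guard regardless.
    n[n == 0.0] = 1.0
    return normals / n


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1),
        ],
        axis=-2,
    )


def quat_from_matrix(m: np.ndarray) -> np.ndarray:
    """Quaternion from a proper rotation matrix (Shepperd's method)."""
    m = np.asarray(m, dtype=float)
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2.0
        return np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    i = int(np.argmax(np.diag(m)))
    j, k = (i + 1) % 3, (i + 2) % 3
    s = np.sqrt(m[i, i] - m[j, j] - m[k, k] + 1.0) * 2.0
    q = np.empty(4)
    q[0] = (m[k, j] - m[j, k]) / s
    q[1 + i] = 0.25 * s
    q[1 + j] = (m[j, i] + m[i, j]) / s
    q[1 + k] = (m[k, i] + m[i, k]) / s
    return q / np.linalg.norm(q)


def frame_alignment_quat(n_from, p_from, n_to, p_to) -> np.ndarray:
    """Rotation taking orthonormal frame (n_from, p_from) onto (n_to, p_to).

    Each pair (normal, in-plane) defines a right-handed frame
    ``[n, p, n x p]``; the returned quaternion maps the first frame exactly
    onto the second.
    """
    n_from = normalize(n_from)
    p_from = normalize(p_from)
    n_to = normalize(n_to)
    p_to = normalize(p_to)
    f = np.column_stack([n_from, p_from, np.cross(n_from, p_from)])
    g = np.column_stack([n_to, p_to, np.cross(n_to, p_to)])
    return quat_from_matrix(g @ f.T)


def twist_about_y(q: np.ndarray) -> tuple[np.ndarray, float]:
    """Swing-twist decomposition of ``q`` about the y axis.

    Returns ``(q_twist, angle)`` where ``q_twist`` is the pure y-rotation
    component of ``q`` (the twist) and ``angle`` its signed angle.
    """
    q = np.asarray(q, dtype=float)
    w, y = q[0], q[2]
    n = np.hypot(w, y)
    if n < 1e-300:
        return IDENTITY_QUAT.copy(), 0.0
    tw = np.array([w / n, 0.0, y / n, 0.0])
    angle = 2.0 * np.arctan2(tw[2], tw[0])
    return tw, angle


def slerp(q: np.ndarray, t: float) -> np.ndarray:
    """Interpolate between the identity and rotation ``q`` (fraction ``t``)."""
    q = np.asarray(q, dtype=float)
    if q[0] < 0:
        q = -q
    w = min(1.0, max(-1.0, q[0]))
    theta = np.arccos(w)
    if theta < 1e-12:
        return IDENTITY_QUAT.copy()
    axis = q[1:] / np.sin(theta)
    half = t * theta
    return np.array([np.cos(half), *(np.sin(half) * axis)])


def rotation_angle(q: np.ndarray) -> float:
    """Magnitude of the rotation angle encoded by ``q`` in [0, pi]."""
    w = abs(float(np.clip(np.asarray(q, dtype=float)[0], -1.0, 1.0)))
    return 2.0 * np.arccos(w)
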
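"""Quaternion algebra for rigid-body kinematics.

Quaternions are stored as numpy arrays of shape ``(..., 4)`` in scalar-first
order ``(w, x, y, z)`` using the Hamilton convention, and encode body->global
rotations.  ``q`` and ``-q`` represent the same rotation; sequences are kept
on one hemisphere by :func:`hemisphere_correct` and single values are
canonicalized to ``w >= 0``.

`scipy.spatial.transform.Rotation` (scalar-last) is used for conversions to
and from rotation matrices and Euler/Cardan angles; the reordering is confined
to this module.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "qnormalize",
    "qconj",
    "qmult",
    "qrotate",
    "canonicalize",
    "hemisphere_correct",
    "to_matrix",
    "from_matrix",
    "from_axis_angle",
    "to_scipy",
    "from_scipy",
    "identity",
]

_UNIT_TOL = 1e-9


def identity(n: int | None = None) -> np.ndarray:
    """Identity quaternion, optionally tiled to ``(n, 4)``."""
    q = np.array([1.0, 0.0, 0.0, 0.0])
    if n is None:
        return q
    return np.tile(q, (n, 1))


def qnormalize(q: np.ndarray) -> np.ndarray:
    """Return unit quaternion(s); raises on zero norm."""
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def qmult(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a ⊗ b, broadcasting over leading axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = (a[..., i] for i in range(4))
    bw, bx, by, bz = (b[..., i] for i in range(4))
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (body->global)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # Rodrigues-style expansion: v' = v + 2 w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Flip sign so the scalar part is non-negative."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def hemisphere_correct(q: np.ndarray) -> np.ndarray:
    """Enforce positive dot products between consecutive quaternions.

    Keeps a quaternion time series continuous (no sign jumps), which is a
    precondition for finite-difference differentiation.
    """
    q = np.array(q, dtype=float, copy=True)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError("expected an (n, 4) quaternion sequence")
    flip = np.cumsum(np.sum(q[1:] * q[:-1], axis=1) < 0) % 2
    q[1:][flip == 1] *= -1.0
    return q


def to_scipy(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def from_scipy(r: Rotation) -> np.ndarray:
    return np.roll(r.as_quat(), 1, axis=-1)


def to_matrix(q: np.ndarray) -> np.ndarray:
    return to_scipy(q).as_matrix()


def from_matrix(m: np.ndarray) -> np.ndarray:
    return from_scipy(Rotation.from_matrix(m))


def from_axis_angle(axis: np.ndarray, angle_rad: float | np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle_rad, dtype=float)[..., None]
    return np.concatenate(
        [np.cos(angle / 2.0), axis * np.sin(angle / 2.0)], axis=-1
    )


def assert_unit(q: np.ndarray, tol: float = 1e-6) -> None:
    err = np.abs(np.linalg.norm(np.asarray(q, float), axis=-1) - 1.0)
    if np.any(err > tol):
        raise ValueError(f"non-unit quaternion (max |norm-1| = {err.max():.3g})")
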
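"""Minimal Hamilton quaternion algebra on NumPy arrays.

Conventions used throughout the package:

* scalar-first storage ``(w, x, y, z)``, arrays of shape ``(..., 4)``;
* Hamilton product (right-handed, ``i*j = k``);
* a quaternion ``q`` maps the *sensor/body* frame into the *earth* frame:
  ``v_earth = q ⊗ v_body ⊗ q*``.  A physical accelerometer or magnetometer
  therefore senses the earth-fixed field rotated by the conjugate of ``q``.

``q`` and ``-q`` encode the same rotation; comparison helpers are
sign-invariant.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "qmul",
    "qconj",
    "qnormalize",
    "qrotate",
    "qrotate_inv",
    "from_axis_angle",
    "from_euler_zyx",
    "from_matrix",
    "to_matrix",
    "sign_align",
    "rotation_angle_between",
    "random_unit",
]

_UNIT_TOL = 1e-6


def _as_quat(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion array must have last dimension 4, got {q.shape}")
    return q


def qmul(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product q1 ⊗ q2, broadcasting over leading dimensions."""
    q1, q2 = _as_quat(q1), _as_quat(q2)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = _as_quat(q)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("cannot normalize a (near-)zero quaternion")
    return q / n


def _check_unit(q: np.ndarray) -> None:
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > _UNIT_TOL):
        raise ValueError(
            f"quaternion norm deviates from 1 by more than {_UNIT_TOL:g} "
            f"(max deviation {np.max(np.abs(n - 1.0)):.3g})"
        )


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q`` (body → earth)."""
    q = _as_quat(q)
    _check_unit(q)
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError("vector array must have last dimension 3")
    # v' = v + 2 s (u × v) + 2 u × (u × v), u = vector part, s = scalar part
    u = q[..., 1:]
    s = q[..., :1]
    uv = np.cross(u, v)
    return v + 2.0 * (s * uv + np.cross(u, uv))


def qrotate_inv(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate ``v`` by the conjugate of ``q`` (earth → body)."""
    return qrotate(qconj(_as_quat(q)), v)


def from_axis_angle(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("rotation axis must be non-zero")
    axis = axis / n
    half = angle / 2.0
    w = np.cos(half)
    xyz = axis * np.sin(half)[..., None]
    return np.concatenate([w[..., None], xyz], axis=-1)


def from_euler_zyx(yaw, pitch, roll) -> np.ndarray:
    """Intrinsic z-y-x (yaw, pitch, roll) Euler angles to quaternion."""
    qz = from_axis_angle(np.array([0.0, 0.0, 1.0]), np.asarray(yaw, dtype=float))
    qy = from_axis_angle(np.array([0.0, 1.0, 0.0]), np.asarray(pitch, dtype=float))
    qx = from_axis_angle(np.array([1.0, 0.0, 0.0]), np.asarray(roll, dtype=float))
    return qmul(qmul(qz, qy), qx)


def to_matrix(q: np.ndarray) -> np.ndarray:
    """Direction-cosine matrix R with ``v_earth = R @ v_body``."""
    q = qnormalize(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], axis=-1)
    row1 = np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], axis=-1)
    row2 = np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def from_matrix(R: np.ndarray) -> np.ndarray:
    """Rotation matrix → unit quaternion (Shepperd's method, branch-free form)."""
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError("rotation matrix array must have trailing shape (3, 3)")
    # four squared components from the diagonal
    t = np.trace(R, axis1=-2, axis2=-1)
    qsq = np.stack(
        [
            1.0 + t,
            1.0 + 2.0 * R[..., 0, 0] - t,
            1.0 + 2.0 * R[..., 1, 1] - t,
            1.0 + 2.0 * R[..., 2, 2] - t,
        ],
        axis=-1,
    )
    qsq = np.clip(qsq, 0.0, None) / 4.0
    i = np.argmax(qsq, axis=-1)

    w = np.empty_like(t)
    x = np.empty_like(t)
    y = np.empty_like(t)
    z = np.empty_like(t)

    def _fill(mask, vals):
        nonlocal w, x, y, z
        if not np.any(mask):
            return
        w[mask], x[mask], y[mask], z[mask] = vals

    m0 = i == 0
    if np.any(m0):
        r = R[m0]
        w0 = np.sqrt(qsq[m0, 0])
        _fill(
            m0,
            (
                w0,
                (r[..., 2, 1] - r[..., 1, 2]) / (4 * w0),
                (r[..., 0, 2] - r[..., 2, 0]) / (4 * w0),
                (r[..., 1, 0] - r[..., 0, 1]) / (4 * w0),
            ),
        )
    m1 = i == 1
    if np.any(m1):
        r = R[m1]
        x1 = np.sqrt(qsq[m1, 1])
        _fill(
            m1,
            (
                (r[..., 2, 1] - r[..., 1, 2]) / (4 * x1),
                x1,
                (r[..., 0, 1] + r[..., 1, 0]) / (4 * x1),
                (r[..., 0, 2] + r[..., 2, 0]) / (4 * x1),
            ),
        )
    m2 = i == 2
    if np.any(m2):
        r = R[m2]
        y2 = np.sqrt(qsq[m2, 2])
        _fill(
            m2,
            (
                (r[..., 0, 2] - r[..., 2, 0]) / (4 * y2),
                (r[..., 0, 1] + r[..., 1, 0]) / (4 * y2),
                y2,
                (r[..., 1, 2] + r[..., 2, 1]) / (4 * y2),
            ),
        )
    m3 = i == 3
    if np.any(m3):
        r = R[m3]
        z3 = np.sqrt(qsq[m3, 3])
        _fill(
            m3,
            (
                (r[..., 1, 0] - r[..., 0, 1]) / (4 * z3),
                (r[..., 0, 2] + r[..., 2, 0]) / (4 * z3),
                (r[..., 1, 2] + r[..., 2, 1]) / (4 * z3),
                z3,
            ),
        )
    return qnormalize(np.stack([w, x, y, z], axis=-1))


def sign_align(qs: np.ndarray) -> np.ndarray:
    """Flip signs along the first axis so consecutive dot products are ≥ 0."""
    qs = _as_quat(qs).copy()
    if qs.ndim < 2:
        return qs
    dots = np.sum(qs[:-1] * qs[1:], axis=-1)
    flips = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    qs[1:] *= flips[:, None]
    return qs


def rotation_angle_between(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Sign-invariant rotation angle (rad) taking q1 into q2.

    Uses the chord length 2·arcsin(‖q1 ∓ q2‖/2), which keeps full floating
    precision for small angles (2·arccos of the dot product loses half the
    significant digits near zero).
    """
    q1, q2 = qnormalize(q1), qnormalize(q2)
    chord = np.minimum(
        np.linalg.norm(q1 - q2, axis=-1), np.linalg.norm(q1 + q2, axis=-1)
    )
    return 4.0 * np.arcsin(np.clip(0.5 * chord, 0.0, 1.0))


def random_unit(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniformly random unit quaternion(s)."""
    shape = (4,) if n is None else (n, 4)
    q = rng.standard_normal(shape)
    return qnormalize(q)
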
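"""Quaternion and hypersphere geometry.

Conventions used throughout the package:

* quaternions are scalar-first ``(q0, q1, q2, q3)`` and unit length;
* rotations are represented on the ``q0 >= 0`` hemisphere of S^3, since
  ``R(q) == R(-q)``;
* hyperspherical angles ``s = (theta0, theta1, theta2)`` parametrize the
  hemisphere as::

      q0 = cos(theta0)                      theta0 in [0, pi/2]
      q1 = sin(theta0) cos(theta1)          theta1 in [0, pi]
      q2 = sin(theta0) sin(theta1) cos(theta2)
      q3 = sin(theta0) sin(theta1) sin(theta2)   theta2 in [0, 2 pi)

  with area element ``sin^2(theta0) sin(theta1)`` relative to the round
  (embedded) metric of S^3.

All functions are vectorized over leading axes.
"""

from __future__ import annotations

import numpy as np

#: lower clip for arguments of logs of the hemisphere area element
AREA_CLIP = 1e-8

TWO_PI = 2.0 * np.pi


def normalize(q: np.ndarray) -> np.ndarray:
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def fix_hemisphere(q: np.ndarray) -> np.ndarray:
    """Map a unit quaternion to its representative with ``q0 >= 0``.

    ``sign(0) = +1``: quaternions with exactly vanishing scalar part are
    returned unchanged (a measure-zero set).
    """
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0.0, -1.0, 1.0)
    return q * sign


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a * b`` (scalar-first)."""
    a0, a1, a2, a3 = np.moveaxis(np.asarray(a, dtype=float), -1, 0)
    b0, b1, b2, b3 = np.moveaxis(np.asarray(b, dtype=float), -1, 0)
    return np.stack(
        [
            a0 * b0 - a1 * b1 - a2 * b2 - a3 * b3,
            a0 * b1 + a1 * b0 + a2 * b3 - a3 * b2,
            a0 * b2 - a1 * b3 + a2 * b0 + a3 * b1,
            a0 * b3 + a1 * b2 - a2 * b1 + a3 * b0,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotation_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a (possibly non-unit) quaternion.

    Non-unit quaternions are normalized first, so the map is constant along
    the radial direction of R^4; this is what makes the numerical J^T J of
    the molecule reconstruction acquire exactly one null eigenvalue.
    """
    q = normalize(np.asarray(q, dtype=float))
    q0, q1, q2, q3 = np.moveaxis(q, -1, 0)
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (q2 * q2 + q3 * q3)
    R[..., 0, 1] = 2 * (q1 * q2 - q0 * q3)
    R[..., 0, 2] = 2 * (q1 * q3 + q0 * q2)
    R[..., 1, 0] = 2 * (q1 * q2 + q0 * q3)
    R[..., 1, 1] = 1 - 2 * (q1 * q1 + q3 * q3)
    R[..., 1, 2] = 2 * (q2 * q3 - q0 * q1)
    R[..., 2, 0] = 2 * (q1 * q3 - q0 * q2)
    R[..., 2, 1] = 2 * (q2 * q3 + q0 * q1)
    R[..., 2, 2] = 1 - 2 * (q1 * q1 + q2 * q2)
    return R


def quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion of a rotation matrix (Shepperd's method), hemisphere-fixed."""
    R = np.asarray(R, dtype=float)
    batch = R.shape[:-2]
    Rf = R.reshape((-1, 3, 3))
    n = Rf.shape[0]
    q = np.empty((n, 4))
    t = np.einsum("nii->n", Rf)
    # candidate squared magnitudes (up to scale) for q0, q1, q2, q3
    cand = np.stack(
        [1.0 + t, 1.0 + 2.0 * Rf[:, 0, 0] - t, 1.0 + 2.0 * Rf[:, 1, 1] - t, 1.0 + 2.0 * Rf[:, 2, 2] - t],
        axis=1,
    )
    best = np.argmax(cand, axis=1)
    for k in range(4):
        idx = np.nonzero(best == k)[0]
        if idx.size == 0:
            continue
        r = Rf[idx]
        s = np.sqrt(np.maximum(cand[idx, k], 1e-300))
        if k == 0:
            q[idx, 0] = s
            q[idx, 1] = (r[:, 2, 1] - r[:, 1, 2]) / s
            q[idx, 2] = (r[:, 0, 2] - r[:, 2, 0]) / s
            q[idx, 3] = (r[:, 1, 0] - r[:, 0, 1]) / s
        elif k == 1:
            q[idx, 0] = (r[:, 2, 1] - r[:, 1, 2]) / s
            q[idx, 1] = s
            q[idx, 2] = (r[:, 0, 1] + r[:, 1, 0]) / s
            q[idx, 3] = (r[:, 0, 2] + r[:, 2, 0]) / s
        elif k == 2:
            q[idx, 0] = (r[:, 0, 2] - r[:, 2, 0]) / s
            q[idx, 1] = (r[:, 0, 1] + r[:, 1, 0]) / s
            q[idx, 2] = s
            q[idx, 3] = (r[:, 1, 2] + r[:, 2, 1]) / s
        else:
            q[idx, 0] = (r[:, 1, 0] - r[:, 0, 1]) / s
            q[idx, 1] = (r[:, 0, 2] + r[:, 2, 0]) / s
            q[idx, 2] = (r[:, 1, 2] + r[:, 2, 1]) / s
            q[idx, 3] = s
    q = normalize(q)
    return fix_hemisphere(q.reshape(batch + (4,)))


def quat_to_hyperspherical(q: np.ndarray) -> np.ndarray:
    """Hyperspherical angles of a hemisphere-fixed unit quaternion.

    At singular points (``sin(theta0) = 0`` or ``sin(theta1) = 0``) the
    undefined downstream angles are set to 0 deterministically.
    """
    q = np.asarray(q, dtype=float)
    q0 = np.clip(q[..., 0], -1.0, 1.0)
    theta0 = np.arccos(q0)
    sin0 = np.sin(theta0)
    safe0 = sin0 > 1e-14
    c1 = np.where(safe0, q[..., 1] / np.where(safe0, sin0, 1.0), 1.0)
    theta1 = np.where(safe0, np.arccos(np.clip(c1, -1.0, 1.0)), 0.0)
    sin1 = np.sin(theta1)
    safe1 = safe0 & (sin1 > 1e-14)
    denom = np.where(safe1, sin0 * sin1, 1.0)
    theta2 = np.where(safe1, np.arctan2(q[..., 3] / denom, q[..., 2] / denom), 0.0)
    theta2 = np.mod(theta2, TWO_PI)
    return np.stack([theta0, theta1, theta2], axis=-1)


def hyperspherical_to_quat(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    t0, t1, t2 = s[..., 0], s[..., 1], s[..., 2]
    sin0, sin1 = np.sin(t0), np.sin(t1)
    return np.stack(
        [np.cos(t0), sin0 * np.cos(t1), sin0 * sin1 * np.cos(t2), sin0 * sin1 * np.sin(t2)],
        axis=-1,
    )


def log_area_element(s: np.ndarray, clip: float = AREA_CLIP) -> np.ndarray:
    """``ln(sin^2(theta0) sin(theta1))`` with both sine factors clipped at ``clip``.

    This is the log-volume of the map s -> q* (hemisphere angles to embedded
    unit vector); the opposite direction carries the negated value.
    """
    s = np.asarray(s, dtype=float)
    sin0 = np.maximum(np.abs(np.sin(s[..., 0])), clip)
    sin1 = np.maximum(np.abs(np.sin(s[..., 1])), clip)
    return 2.0 * np.log(sin0) + np.log(sin1)


def chordal_mean_quat(q: np.ndarray, axis: int = 0) -> np.ndarray:
    """Chordal (Karcher-free) mean: principal eigenvector of the averaged outer product."""
    q = np.asarray(q, dtype=float)
    q = np.moveaxis(q, axis, 0)
    M = np.einsum("n...i,n...j->...ij", q, q) / q.shape[0]
    w, v = np.linalg.eigh(M)
    mean = v[..., -1]
    return fix_hemisphere(normalize(mean))


def random_hemisphere_quat(rng: np.random.Generator, shape=()) -> np.ndarray:
    """Uniform samples on the ``q0 >= 0`` hemisphere of S^3."""
    q = rng.standard_normal(tuple(shape) + (4,))
    return fix_hemisphere(normalize(q))
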
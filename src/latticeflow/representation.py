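"""Transformations between supercell Cartesian coordinates and flow variables.

All maps here are exactly invertible away from singular geometries, and every
map reports its log-volume change so that densities can be transported
through the chain. Directions follow the flow convention: ``to_base`` means
Cartesian configuration -> flow variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from . import geometry
from .frames import Ensemble, SupercellFrame, Topology

__all__ = [
    "LogVolume",
    "MoleculeInternal",
    "RepresentationError",
    "remove_oxygen_com",
    "reconstruct_virtual_site",
    "drop_virtual_site",
    "molecule_to_internal",
    "internal_to_molecule",
    "internal_log_volume",
    "molecules_to_internal_batch",
    "internal_to_molecules_batch",
    "fix_hemisphere",
    "quaternion_to_hyperspherical",
    "hyperspherical_to_quaternion",
    "align_reference_rotations",
    "apply_rotation_offsets",
    "invert_rotation_offsets",
]

fix_hemisphere = geometry.fix_hemisphere


class RepresentationError(ValueError):
    """Raised for geometries where the internal-coordinate map is singular."""


@dataclass
class LogVolume:
    """Accumulated log-Jacobian of a transformation chain.

    ``direction`` is ``"to_base"`` (configuration -> flow variables) or
    ``"from_base"``; for any invertible chain the two directions sum to zero.
    """

    value: np.ndarray
    direction: str = "to_base"

    def __post_init__(self) -> None:
        if self.direction not in ("to_base", "from_base"):
            raise ValueError("direction must be 'to_base' or 'from_base'")


@dataclass
class MoleculeInternal:
    """Internal coordinates of one water molecule.

    ``d1, d2`` are the O-H bond lengths (nm), ``theta`` the H-O-H angle (rad)
    and ``q`` the unit quaternion (scalar-first, hemisphere-fixed) rotating
    the canonical molecule frame into the lab frame.
    """

    d1: float
    d2: float
    theta: float
    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not (self.d1 > 0 and self.d2 > 0):
            raise ValueError("bond lengths must be positive")
        if not (0.0 < self.theta < np.pi):
            raise ValueError("bond angle must lie strictly between 0 and pi")
        if abs(np.linalg.norm(self.q) - 1.0) > 1e-12:
            raise ValueError("quaternion must be unit length")
        if self.q[0] < 0:
            raise ValueError("quaternion must be hemisphere-fixed (q0 >= 0)")


# ---------------------------------------------------------------------------
# center of mass and virtual sites
# ---------------------------------------------------------------------------

def oxygen_centroid(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Mass-weighted centroid of the oxygen atoms (masses are equal, so this
    coincides with the plain centroid; kept mass-weighted for generality)."""
    idx = topology.role_indices("O")
    m = topology.masses["O"] * np.ones(len(idx))
    return np.einsum("...ax,a->...x", coords[..., idx, :], m / m.sum())


def remove_oxygen_com(frame):
    """Shift every atom so the oxygen centroid is exactly the zero vector.

    Periodic images are expected to be unwrapped already; periodic boundary
    conditions are not taken into account here. Works on a single frame or an
    ensemble and returns the same type.
    """
    if isinstance(frame, SupercellFrame):
        com = oxygen_centroid(frame.coords, frame.topology)
        return SupercellFrame(frame.coords - com, frame.box, frame.topology, frame.temperature)
    if isinstance(frame, Ensemble):
        com = oxygen_centroid(frame.coords, frame.topology)
        return Ensemble(frame.coords - com[:, None, :], frame.box, frame.topology, frame.temperature)
    raise TypeError("expected SupercellFrame or Ensemble")


def reconstruct_virtual_site(frame, weights) -> "SupercellFrame | Ensemble":
    """Add the virtual site ``r_M = w_O r_O + w_H r_H1 + w_H r_H2`` per molecule."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or abs(w.sum() - 1.0) > 1e-10:
        raise ValueError("virtual-site weights must be 3 scalars summing to 1")
    topo = frame.topology
    if topo.has_virtual_site:
        raise ValueError("frame already carries virtual sites")
    coords = np.asarray(frame.coords, dtype=float)
    mols = coords.reshape(coords.shape[:-2] + (topo.n_mol, 3, 3))
    rm = np.einsum("...mkx,k->...mx", mols, w)
    out = np.concatenate([mols, rm[..., None, :]], axis=-2)
    out = out.reshape(coords.shape[:-2] + (topo.n_mol * 4, 3))
    new_topo = topo.with_virtual_site(w)
    if isinstance(frame, SupercellFrame):
        return SupercellFrame(out, frame.box, new_topo, frame.temperature)
    return Ensemble(out, frame.box, new_topo, frame.temperature)


def drop_virtual_site(frame):
    """Remove virtual sites; the inverse of :func:`reconstruct_virtual_site`."""
    topo = frame.topology
    if not topo.has_virtual_site:
        return frame
    coords = np.asarray(frame.coords, dtype=float)
    mols = coords.reshape(coords.shape[:-2] + (topo.n_mol, 4, 3))[..., :3, :]
    out = mols.reshape(coords.shape[:-2] + (topo.n_mol * 3, 3))
    new_topo = topo.without_virtual_site()
    if isinstance(frame, SupercellFrame):
        return SupercellFrame(out, frame.box, new_topo, frame.temperature)
    return Ensemble(out, frame.box, new_topo, frame.temperature)


# ---------------------------------------------------------------------------
# internal coordinates of a water molecule
# ---------------------------------------------------------------------------

def internal_log_volume(d1, d2, theta) -> np.ndarray:
    """Closed-form log-volume of reconstructing (r_H1, r_H2) from
    (d1, d2, theta, q on S^3): ``ln(8 d1^2 d2^2 sin(theta))``.

    This equals ``(1/2) sum_i ln(lambda_i)`` over the nonzero eigenvalues of
    J^T J of the reconstruction map; the opposite direction carries the
    negated value.
    """
    return np.log(8.0) + 2.0 * np.log(d1) + 2.0 * np.log(d2) + np.log(np.sin(theta))


_SIN_TOL = 1e-10


def _internals_from_vectors(v1: np.ndarray, v2: np.ndarray):
    """Vectorized core: bond vectors (..., 3) -> d1, d2, theta, q."""
    d1 = np.linalg.norm(v1, axis=-1)
    d2 = np.linalg.norm(v2, axis=-1)
    if np.any(d1 <= _SIN_TOL) or np.any(d2 <= _SIN_TOL):
        raise RepresentationError("zero-length bond")
    u1 = v1 / d1[..., None]
    u2 = v2 / d2[..., None]
    cos_t = np.clip(np.einsum("...x,...x->...", u1, u2), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sin(theta)
    if np.any(sin_t <= _SIN_TOL):
        raise RepresentationError("collinear molecule geometry")
    e2 = (u2 - cos_t[..., None] * u1) / sin_t[..., None]
    e3 = np.cross(u1, e2)
    R = np.stack([u1, e2, e3], axis=-1)  # columns
    q = geometry.quat_from_matrix(R)
    return d1, d2, theta, q


def _vectors_from_internals(d1, d2, theta, q):
    R = geometry.rotation_matrix(q)
    a = np.stack([d1, np.zeros_like(d1), np.zeros_like(d1)], axis=-1)
    b = np.stack([d2 * np.cos(theta), d2 * np.sin(theta), np.zeros_like(d2)], axis=-1)
    v1 = np.einsum("...xy,...y->...x", R, a)
    v2 = np.einsum("...xy,...y->...x", R, b)
    return v1, v2


def molecule_to_internal(r_mol: np.ndarray) -> Tuple[MoleculeInternal, LogVolume]:
    """Map one molecule's (O, H1, H2) positions to internal coordinates.

    The canonical molecule frame places H1 along +x at distance d1 and H2 in
    the xy-plane at angle theta, with O at the origin; ``q`` is the rotation
    carrying that frame into the lab frame. The returned log-volume is in the
    configuration -> internal direction.
    """
    r = np.asarray(r_mol, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("expected three atom positions (3, 3)")
    d1, d2, theta, q = _internals_from_vectors(r[1] - r[0], r[2] - r[0])
    lv = -internal_log_volume(d1, d2, theta)
    return MoleculeInternal(float(d1), float(d2), float(theta), q), LogVolume(lv, "to_base")


def internal_to_molecule(r_o: np.ndarray, internal: MoleculeInternal) -> Tuple[np.ndarray, LogVolume]:
    """Inverse of :func:`molecule_to_internal`; returns (O, H1, H2) positions."""
    v1, v2 = _vectors_from_internals(internal.d1, internal.d2, internal.theta, internal.q)
    r_o = np.asarray(r_o, dtype=float)
    coords = np.stack([r_o, r_o + v1, r_o + v2])
    lv = internal_log_volume(internal.d1, internal.d2, internal.theta)
    return coords, LogVolume(lv, "from_base")


def molecules_to_internal_batch(coords: np.ndarray, topology: Topology):
    """All molecules of an ensemble to internals.

    Parameters
    ----------
    coords : (F, n_atoms, 3) without virtual sites.

    Returns
    -------
    r_o : (F, n_mol, 3); d1, d2, theta : (F, n_mol); q : (F, n_mol, 4);
    logvol : (F,) summed per frame, configuration -> internal direction.
    """
    if topology.has_virtual_site:
        raise ValueError("drop virtual sites before the internal-coordinate map")
    mols = coords.reshape(coords.shape[0], topology.n_mol, 3, 3)
    r_o = mols[:, :, 0]
    d1, d2, theta, q = _internals_from_vectors(mols[:, :, 1] - r_o, mols[:, :, 2] - r_o)
    logvol = -internal_log_volume(d1, d2, theta).sum(axis=-1)
    return r_o, d1, d2, theta, q, logvol


def internal_to_molecules_batch(r_o, d1, d2, theta, q):
    """Inverse of :func:`molecules_to_internal_batch`.

    Returns (coords (F, 3 n_mol, 3), logvol (F,)) with logvol in the
    internal -> configuration direction.
    """
    v1, v2 = _vectors_from_internals(d1, d2, theta, q)
    mols = np.stack([r_o, r_o + v1, r_o + v2], axis=2)
    coords = mols.reshape(r_o.shape[0], -1, 3)
    logvol = internal_log_volume(d1, d2, theta).sum(axis=-1)
    return coords, logvol


# ---------------------------------------------------------------------------
# hemisphere angles
# ---------------------------------------------------------------------------

def quaternion_to_hyperspherical(q: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Hemisphere-fixed quaternion(s) -> hyperspherical angles.

    Returns ``(s, logvol)`` with logvol in the q* -> s direction, i.e. the
    negated area element ``-ln(sin^2 theta0 sin theta1)`` (clipped).
    """
    s = geometry.quat_to_hyperspherical(q)
    return s, -geometry.log_area_element(s)


def hyperspherical_to_quaternion(s: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Inverse map; logvol is ``+ln(sin^2 theta0 sin theta1)`` (clipped)."""
    return geometry.hyperspherical_to_quat(s), geometry.log_area_element(s)


# ---------------------------------------------------------------------------
# per-molecule reference-rotation alignment
# ---------------------------------------------------------------------------

#: hemisphere angles every site's mean orientation is moved to: centered in
#: theta0 (away from the pole and the hemisphere edge) and in theta1/theta2.
ALIGNMENT_TARGET = np.array([np.pi / 4.0, np.pi / 2.0, np.pi])

#: below this top eigenvalue of the averaged quaternion outer product the
#: site is considered rotationally diffuse (1.0 = perfectly concentrated,
#: 0.25 = uniform).
DISPERSION_THRESHOLD = 0.7


def align_reference_rotations(q: np.ndarray, target: np.ndarray = ALIGNMENT_TARGET):
    """One fixed offset rotation per lattice site.

    ``q`` has shape (F, n_mol, 4), hemisphere-fixed. The offset left-composes
    each site's chordal-mean orientation to the fixed target orientation
    (theta0 = pi/4 by default), so the aligned theta0 marginal is centered
    away from both singular edges. Offsets are fixed after this call and must
    be applied identically to training, validation and generated data.
    """
    q = np.asarray(q, dtype=float)
    qn = q / np.linalg.norm(q, axis=-1, keepdims=True)
    M = np.einsum("fmi,fmj->mij", qn, qn) / q.shape[0]
    w = np.linalg.eigvalsh(M)[:, -1]
    if np.any(w < DISPERSION_THRESHOLD):
        bad = np.nonzero(w < DISPERSION_THRESHOLD)[0]
        warnings.warn(
            f"rotationally diffuse lattice site(s) {bad.tolist()}: "
            "mean-quaternion dispersion above threshold; offsets still produced",
            RuntimeWarning,
        )
    mean = geometry.chordal_mean_quat(q, axis=0)  # (n_mol, 4)
    q_target = geometry.hyperspherical_to_quat(np.asarray(target, dtype=float))
    offsets = geometry.quat_multiply(q_target, geometry.quat_conjugate(mean))
    return geometry.normalize(offsets)


def apply_rotation_offsets(q: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Left-compose per-site offsets and re-fix the hemisphere (a measure-
    preserving isometry of S^3; log-volume 0)."""
    return geometry.fix_hemisphere(geometry.quat_multiply(offsets, q))


def invert_rotation_offsets(q: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    return geometry.fix_hemisphere(geometry.quat_multiply(geometry.quat_conjugate(offsets), q))
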
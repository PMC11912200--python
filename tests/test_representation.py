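import numpy as np
import pytest

from latticeflow import geometry, representation
from latticeflow.frames import Ensemble, SupercellFrame, Topology
from latticeflow.representation import (RepresentationError, internal_log_volume,
                                        internal_to_molecule, molecule_to_internal)


def random_molecules(rng, n):
    """Well-separated random (O, H1, H2) geometries."""
    d1 = rng.uniform(0.08, 0.12, n)
    d2 = rng.uniform(0.08, 0.12, n)
    theta = rng.uniform(0.5, np.pi - 0.5, n)
    q = geometry.random_hemisphere_quat(rng, (n,))
    v1, v2 = representation._vectors_from_internals(d1, d2, theta, q)
    r_o = rng.standard_normal((n, 3))
    return np.stack([r_o, r_o + v1, r_o + v2], axis=1), (d1, d2, theta, q)


def test_molecule_internal_roundtrip():
    rng = np.random.default_rng(0)
    mols, (d1, d2, theta, q) = random_molecules(rng, 200)
    for i in range(20):
        internal, lv = molecule_to_internal(mols[i])
        assert np.isclose(internal.d1, d1[i])
        assert np.isclose(internal.d2, d2[i])
        assert np.isclose(internal.theta, theta[i])
        assert np.allclose(internal.q, q[i], atol=1e-10)
        coords, lv_back = internal_to_molecule(mols[i, 0], internal)
        assert np.allclose(coords, mols[i], atol=1e-12)
        # log-volumes of the two directions cancel exactly
        assert np.isclose(lv.value + lv_back.value, 0.0, atol=1e-12)


def test_collinear_molecule_raises():
    r = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.2, 0, 0]])
    with pytest.raises(RepresentationError):
        molecule_to_internal(r)


def test_internal_log_volume_matches_numerical_jacobian():
    """Closed form ln(8 d1^2 d2^2 sin theta) vs the J^T J spectrum of the
    reconstruction map over (d1, d2, theta, tangent of S^3), 1000 molecules."""
    rng = np.random.default_rng(1)
    n = 1000
    d1 = rng.uniform(0.07, 0.13, n)
    d2 = rng.uniform(0.07, 0.13, n)
    theta = rng.uniform(0.4, np.pi - 0.4, n)
    q = geometry.random_hemisphere_quat(rng, (n,))

    def recon(params, qt):
        dd1, dd2, th = params
        v1, v2 = representation._vectors_from_internals(
            np.asarray(dd1), np.asarray(dd2), np.asarray(th), qt)
        return np.concatenate([np.atleast_2d(v1).ravel(), np.atleast_2d(v2).ravel()])

    eps = 1e-6
    max_err = 0.0
    for i in range(n):
        # orthonormal tangent basis of S^3 at q[i]
        basis = np.linalg.svd(q[i][None, :])[2][1:]  # 3 vectors orthogonal to q
        cols = []
        for k in range(3):
            p = np.array([d1[i], d2[i], theta[i]])
            pp, pm = p.copy(), p.copy()
            pp[k] += eps
            pm[k] -= eps
            cols.append((recon(pp, q[i]) - recon(pm, q[i])) / (2 * eps))
        for b in basis:
            qp = geometry.normalize(q[i] + eps * b)
            qm = geometry.normalize(q[i] - eps * b)
            cols.append((recon((d1[i], d2[i], theta[i]), qp)
                         - recon((d1[i], d2[i], theta[i]), qm)) / (2 * eps))
        J = np.stack(cols, axis=1)  # (6, 6)
        num = 0.5 * np.linalg.slogdet(J.T @ J)[1]
        closed = internal_log_volume(d1[i], d2[i], theta[i])
        max_err = max(max_err, abs(num - closed))
    assert max_err < 1e-6, f"max deviation {max_err:.2e}"


def test_virtual_site_degenerate_weights():
    topo = Topology(2)
    rng = np.random.default_rng(2)
    mols, _ = random_molecules(rng, 2)
    frame = SupercellFrame(mols.reshape(-1, 3), np.eye(3), topo, 100.0)
    out = representation.reconstruct_virtual_site(frame, (1.0, 0.0, 0.0))
    m_idx = out.topology.role_indices("M")
    o_idx = out.topology.role_indices("O")
    assert np.allclose(out.coords[m_idx], out.coords[o_idx])
    back = representation.drop_virtual_site(out)
    assert np.allclose(back.coords, frame.coords)


def test_virtual_site_tip4p_ice_geometry():
    """With weights computed from the published TIP4P/Ice geometry the site
    lands on the H-O-H bisector at the O-M distance of 0.01577 nm."""
    d_oh, theta, d_om = 0.09572, np.deg2rad(104.52), 0.01577
    w_h = d_om / (2 * d_oh * np.cos(theta / 2))
    weights = (1 - 2 * w_h, w_h, w_h)
    r = np.array([[0.0, 0, 0],
                  [d_oh * np.cos(theta / 2), d_oh * np.sin(theta / 2), 0.0],
                  [d_oh * np.cos(theta / 2), -d_oh * np.sin(theta / 2), 0.0]])
    topo = Topology(1)
    frame = SupercellFrame(r, np.eye(3), topo, 100.0)
    out = representation.reconstruct_virtual_site(frame, weights)
    r_m = out.coords[3]
    assert np.isclose(np.linalg.norm(r_m), d_om, atol=1e-12)        # O-M distance
    bisector = np.array([1.0, 0.0, 0.0])
    assert np.isclose(np.dot(r_m / np.linalg.norm(r_m), bisector), 1.0, atol=1e-12)


def test_virtual_site_weight_validation():
    topo = Topology(1)
    frame = SupercellFrame(np.zeros((3, 3)) + np.eye(3), np.eye(3), topo, 100.0)
    with pytest.raises(ValueError):
        representation.reconstruct_virtual_site(frame, (0.5, 0.5, 0.5))


def test_remove_oxygen_com():
    topo = Topology(3)
    rng = np.random.default_rng(3)
    mols, _ = random_molecules(rng, 3)
    ens = Ensemble(mols.reshape(1, -1, 3) + 5.0, np.eye(3), topo, 100.0)
    out = representation.remove_oxygen_com(ens)
    o_idx = topo.role_indices("O")
    assert np.allclose(out.coords[:, o_idx].mean(axis=1), 0.0, atol=1e-12)


def test_batch_roundtrip_and_logvol_cancellation():
    topo = Topology(8)
    rng = np.random.default_rng(4)
    mols, _ = random_molecules(rng, 8 * 10)
    coords = mols.reshape(10, -1, 3)
    r_o, d1, d2, th, q, lv = representation.molecules_to_internal_batch(coords, topo)
    coords2, lv_back = representation.internal_to_molecules_batch(r_o, d1, d2, th, q)
    assert np.allclose(coords, coords2, atol=1e-12)
    assert np.allclose(lv + lv_back, 0.0, atol=1e-10)


def test_rotation_offsets_center_the_angles():
    rng = np.random.default_rng(5)
    n_frames, n_mol = 400, 6
    center = geometry.random_hemisphere_quat(rng, (n_mol,))
    noise = rng.standard_normal((n_frames, n_mol, 4)) * 0.05
    q = geometry.fix_hemisphere(geometry.normalize(center + noise))
    offsets = representation.align_reference_rotations(q)
    q_al = representation.apply_rotation_offsets(q, offsets)
    s = geometry.quat_to_hyperspherical(q_al)
    # aligned mean angles sit near the fixed target, away from chart edges
    assert np.allclose(s.mean(axis=0), representation.ALIGNMENT_TARGET, atol=0.1)
    back = representation.invert_rotation_offsets(q_al, offsets)
    # inversion recovers the rotation (up to hemisphere sign, already fixed)
    assert np.allclose(np.abs(np.einsum("fmi,fmi->fm", back, q)), 1.0, atol=1e-10)


def test_diffuse_rotations_warn():
    rng = np.random.default_rng(6)
    q = geometry.random_hemisphere_quat(rng, (500, 2))
    with pytest.warns(RuntimeWarning):
        representation.align_reference_rotations(q)


def test_quaternion_to_hyperspherical_logvol_direction():
    rng = np.random.default_rng(7)
    q = geometry.random_hemisphere_quat(rng, (100,))
    s, lv = representation.quaternion_to_hyperspherical(q)
    q2, lv_back = representation.hyperspherical_to_quaternion(s)
    assert np.allclose(q, q2, atol=1e-12)
    assert np.allclose(lv + lv_back, 0.0, atol=1e-12)
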
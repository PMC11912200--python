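import numpy as np
import pytest
from scipy.stats import norm

from latticeflow.fixtures import (HarmonicCrystalSpec, TwoPolymorphFixture,
                                  _grid_dims, sample_fixture,
                                  two_polymorph_fixture)


def test_grid_dims_near_cubic():
    assert _grid_dims(8) == (2, 2, 2)
    assert _grid_dims(16) == (2, 2, 4)
    assert _grid_dims(64) == (4, 4, 4)
    assert _grid_dims(7) == (1, 1, 7)  # primes degrade gracefully


def test_spec_validation_and_warning():
    with pytest.raises(ValueError):
        HarmonicCrystalSpec(n_mol=1)
    with pytest.raises(ValueError):
        HarmonicCrystalSpec(k_bond=-1.0)
    with pytest.warns(RuntimeWarning, match="hemisphere"):
        HarmonicCrystalSpec(k_rot=0.5)


def test_sites_have_zero_centroid_and_box_consistency():
    spec = HarmonicCrystalSpec(n_mol=16)
    assert np.allclose(spec.sites.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(np.diag(spec.box), np.array(spec.grid) * spec.lattice_spacing)


def test_reference_coords_minimize_the_potential():
    spec = HarmonicCrystalSpec(n_mol=4)
    ref = spec.reference_coords
    # at the mean structure every quadratic mode sits at its minimum; the
    # remaining value is the log-measure part (Jacobian + area element)
    b_u = spec.beta_potential(ref)
    rng = np.random.default_rng(0)
    ens, b_u_samp, _ = sample_fixture(spec, 50, rng)
    assert np.all(b_u_samp > b_u)


def test_mode_variances_match_springs():
    """Sampled internal modes reproduce the 1/(beta k) variances."""
    spec = HarmonicCrystalSpec(n_mol=8)
    rng = np.random.default_rng(1)
    modes = spec.sample_internal_modes(4000, rng)
    b = spec.beta
    for k, bk in [(0, b * spec.k_bond), (2, b * spec.k_theta), (3, b * spec.k_rot)]:
        var = modes[..., k].var()
        assert np.isclose(var, 1.0 / bk, rtol=0.1), (k, var, 1.0 / bk)


def test_oxygen_sampler_respects_centroid_and_covariance():
    spec = HarmonicCrystalSpec(n_mol=8)
    rng = np.random.default_rng(2)
    r_o = spec.sample_oxygens(6000, rng)
    assert np.allclose(r_o.mean(axis=1), 0.0, atol=1e-12)
    # centroid-conditioned marginal variance: (1 - 1/n) / (beta k)
    dev = r_o - spec.sites
    var = dev.var()
    expected = (1.0 - 1.0 / spec.n_mol) / spec.bk_site[0]
    assert np.isclose(var, expected, rtol=0.05)


def test_equipartition_of_quadratic_modes():
    """<quadratic betaU> = (9 n - 3)/2: half per constrained quadratic mode."""
    spec = HarmonicCrystalSpec(n_mol=8)
    rng = np.random.default_rng(3)
    ens, _, _ = sample_fixture(spec, 4000, rng)
    quad = spec.quadratic_mode_energy(ens.coords)
    dof = 9 * spec.n_mol - 3
    se = quad.std(ddof=1) / np.sqrt(quad.size)
    assert abs(quad.mean() - dof / 2) < 4 * se, (quad.mean(), dof / 2, se)


def test_mean_potential_and_entropy_identity():
    """Sampled <betaU> matches the quadrature value, and the entropy identity
    s = (<betaU> - f)/n holds by construction."""
    spec = HarmonicCrystalSpec(n_mol=8)
    rng = np.random.default_rng(4)
    ens, beta_u, f = sample_fixture(spec, 4000, rng)
    se = beta_u.std(ddof=1) / np.sqrt(beta_u.size)
    assert abs(beta_u.mean() - spec.analytic_mean_potential()) < 4 * se
    s = spec.analytic_entropy_per_molecule()
    assert np.isclose(s, (spec.analytic_mean_potential() - f) / spec.n_mol)


def test_free_energy_by_direct_importance_check():
    """The normalized log density integrates to one: on exact samples,
    <log p + betaU> equals f exactly (a tautology), but the stronger check is
    that the normal-mass normalizer matches a brute-force quadrature."""
    spec = HarmonicCrystalSpec(n_mol=4)
    from scipy import integrate
    # quadrature of one bond mode's truncated normalizer vs the cdf form
    mu, bk, a, b = spec._modes()[0]
    s = 1.0 / np.sqrt(bk)
    direct, _ = integrate.quad(
        lambda x: np.exp(-0.5 * bk * (x - mu) ** 2), max(a, mu - 12 * s), mu + 12 * s)
    cdf_form = np.sqrt(2 * np.pi / bk) * (norm.cdf((b - mu) / s) - norm.cdf((a - mu) / s))
    assert np.isclose(direct, cdf_form, rtol=1e-10)


def test_general_site_springs_match_equal_spring_shortcut():
    """The restricted-determinant oxygen normalizer agrees with the closed
    form when all springs are equal, and shifts correctly when they are not."""
    spec_eq = HarmonicCrystalSpec(n_mol=6)
    explicit = HarmonicCrystalSpec(n_mol=6, site_springs=np.full(6, spec_eq.k_site) * (1 + 1e-12))
    assert np.isclose(spec_eq.log_z_oxygen(), explicit.log_z_oxygen(), rtol=1e-9)
    uneven = HarmonicCrystalSpec(n_mol=6, site_springs=np.array([1, 2, 3, 4, 5, 6]) * 1e4)
    # stiffer average spring -> smaller partition function
    assert uneven.log_z_oxygen() < spec_eq.log_z_oxygen()


def test_sampled_log_density_is_consistent():
    spec = HarmonicCrystalSpec(n_mol=4)
    rng = np.random.default_rng(5)
    ens, beta_u, f = sample_fixture(spec, 100, rng)
    assert np.allclose(spec.log_density(ens.coords), -beta_u + f)
    assert np.all(np.isfinite(beta_u))


def test_hydrogen_energy_degenerate_geometries_are_infinite():
    spec = HarmonicCrystalSpec(n_mol=2)
    v = np.array([0.1, 0.0, 0.0])
    assert np.isinf(spec.hydrogen_energy(v, v))          # collinear
    assert np.isinf(spec.hydrogen_energy(v, np.zeros(3)))  # zero bond


def test_seeded_sampling_is_reproducible():
    spec = HarmonicCrystalSpec(n_mol=4, seed=7)
    e1, b1, _ = sample_fixture(spec, 10)
    e2, b2, _ = sample_fixture(spec, 10)
    assert np.array_equal(e1.coords, e2.coords)
    assert np.array_equal(b1, b2)


def test_two_polymorph_identical_specs_have_zero_gaps():
    a = HarmonicCrystalSpec(n_mol=4)
    b = HarmonicCrystalSpec(n_mol=4)
    fix = two_polymorph_fixture(a, b)
    assert fix.delta_f == 0.0
    assert fix.delta_s_per_molecule == 0.0


def test_two_polymorph_site_stiffness_ratio_closed_form():
    """Polymorphs differing only in the oxygen spring have
    delta f = (3 (n - 1) / 2) ln(k_A / k_B)."""
    a = HarmonicCrystalSpec(n_mol=8, k_site=2.0e4)
    b = HarmonicCrystalSpec(n_mol=8, k_site=1.0e4)
    fix = two_polymorph_fixture(a, b)
    expected = 1.5 * (8 - 1) * np.log(2.0)
    assert np.isclose(fix.delta_f, expected, atol=1e-10)
    with pytest.raises(ValueError):
        two_polymorph_fixture(a, HarmonicCrystalSpec(n_mol=4))


def test_two_polymorph_sampling_returns_both():
    a = HarmonicCrystalSpec(n_mol=4, k_site=2.0e4)
    b = HarmonicCrystalSpec(n_mol=4)
    rng = np.random.default_rng(8)
    (ens_a, bu_a, f_a), (ens_b, bu_b, f_b) = two_polymorph_fixture(a, b).sample(5, rng)
    assert len(ens_a) == len(ens_b) == 5
    assert np.isclose(f_a - f_b, two_polymorph_fixture(a, b).delta_f)
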
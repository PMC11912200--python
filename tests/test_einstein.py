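import numpy as np
import pytest

from latticeflow import einstein
from latticeflow.einstein import (ECMConfig, LambdaChain, analytic_f0,
                                  chain_free_energy, ecm_potential,
                                  einstein_energy, lambda_schedule,
                                  physical_sampling_fraction,
                                  sample_chain_fixture)
from latticeflow.fixtures import HarmonicCrystalSpec, sample_fixture
from latticeflow.frames import Topology


def make_config(n_mol=4, seed=0, **kw):
    spec = HarmonicCrystalSpec(n_mol=n_mol, seed=seed)
    r0 = spec.reference_coords
    return spec, ECMConfig(r0=r0, topology=spec.topology,
                           temperature=spec.temperature, **kw)


def test_lambda_schedule_properties():
    lam = lambda_schedule()
    assert lam.size == 20
    assert lam[0] == 0.0 and lam[-1] == 1.0
    assert np.all(np.diff(lam) > 0)
    # denser near the interacting end
    assert np.diff(lam)[-1] < np.diff(lam)[0]
    # exponent 1 recovers even spacing
    assert np.allclose(np.diff(lambda_schedule(11, exponent=1.0)), 0.1)
    with pytest.raises(ValueError):
        lambda_schedule(1)


def test_config_validation():
    spec, config = make_config()
    with pytest.raises(ValueError, match="centroid"):
        ECMConfig(r0=config.r0 + 0.05, topology=spec.topology,
                  temperature=spec.temperature)
    with pytest.raises(ValueError, match="positive"):
        ECMConfig(r0=config.r0, topology=spec.topology,
                  temperature=spec.temperature, k=-1.0)
    with pytest.raises(ValueError, match="schedule"):
        ECMConfig(r0=config.r0, topology=spec.topology,
                  temperature=spec.temperature, lambdas=np.array([0.0, 0.5, 0.4, 1.0]))


def test_einstein_energy_known_value():
    spec, config = make_config()
    coords = config.r0.copy()
    assert einstein_energy(coords, config) == 0.0
    coords2 = coords.copy()
    coords2[0, 0] += 0.01  # one atom displaced by 0.01 nm
    expected = 0.5 * config.k * 0.01 ** 2
    assert np.isclose(einstein_energy(coords2, config), expected)


def test_ecm_potential_endpoints_and_com_check():
    spec, config = make_config()
    rng = np.random.default_rng(1)
    ens, beta_u, _ = sample_fixture(spec, 5, rng)
    coords = ens.coords
    u_phys = beta_u / spec.beta
    u0 = ecm_potential(0.0, coords, u_phys, config)
    assert np.allclose(u0, einstein_energy(coords, config))
    u1 = ecm_potential(1.0, coords, u_phys, config)
    assert np.allclose(u1, u_phys)
    with pytest.raises(ValueError, match="lambda"):
        ecm_potential(1.5, coords, u_phys, config)
    with pytest.raises(ValueError, match="centroid"):
        ecm_potential(0.5, coords + 0.1, u_phys, config)


def test_analytic_f0_constrained_formula_and_k_scaling():
    spec, config = make_config()
    n_atoms = spec.topology.n_real_atoms
    bk = config.beta * config.k
    assert np.isclose(analytic_f0(config),
                      -1.5 * (n_atoms - 1) * np.log(2 * np.pi / bk))
    # doubling the spring stiffens the crystal by (3 (N - 1) / 2) ln 2
    _, config2 = make_config(k=2 * config.k)
    assert np.isclose(analytic_f0(config2) - analytic_f0(config),
                      1.5 * (n_atoms - 1) * np.log(2.0))


def test_analytic_f0_standard_convention():
    spec, config = make_config()
    vol = float(np.prod(np.diag(spec.box)))
    f_std = analytic_f0(config, volume=vol, convention="standard")
    bk = config.beta * config.k
    n_atoms = spec.topology.n_real_atoms
    m = config.normalized_masses
    expected = (-1.5 * n_atoms * np.log(2 * np.pi / bk)
                + 1.5 * np.log(2 * np.pi * np.sum(m ** 2) / bk)
                - np.log(vol))
    assert np.isclose(f_std, expected)
    assert np.isclose(m.sum(), 1.0)
    with pytest.raises(ValueError, match="volume"):
        analytic_f0(config, convention="standard")
    with pytest.raises(ValueError, match="convention"):
        analytic_f0(config, convention="other")


def test_equal_mass_com_correction_simplifies():
    """With all real atoms at equal mass the COM correction uses
    sum m_i^2 = 1/N, so standard = constrained + box/COM bookkeeping."""
    spec, config = make_config()
    n_atoms = spec.topology.n_real_atoms
    config.topology.masses = {r: 1.0 for r in config.topology.masses}
    m = config.normalized_masses
    assert np.isclose(np.sum(m ** 2), 1.0 / n_atoms)


def test_degenerate_chain_returns_f0():
    """If the physical potential coincides with the tether, every bridge is
    exactly zero and the chain returns the analytic reference."""
    spec, config = make_config()
    lam = config.lambdas
    chain = LambdaChain(lambdas=lam, du=[np.zeros(100) for _ in lam])
    est = chain_free_energy(chain, config)
    assert np.isclose(est.f, analytic_f0(config), atol=1e-9)
    assert est.se < 1e-6
    assert not any(est.diagnostics["overlap_flags"])


def test_chain_gaussian_oracle():
    """Physical potential proportional to the tether: the chain total must
    reproduce (3 (N - 1) / 2) ln a for U_phys = a U_EC."""
    spec, config = make_config()
    a = 1.5
    rng = np.random.default_rng(2)
    n_mol, n_samp = spec.n_mol, 3000
    r0 = config.r0.reshape(n_mol, 3, 3)
    bk = config.beta * config.k
    du = []
    for lam in config.lambdas:
        prec = bk * ((1 - lam) + lam * a)
        mols = r0 + rng.standard_normal((n_samp, n_mol, 3, 3)) / np.sqrt(prec)
        mols[..., 0, :] -= mols[..., 0, :].mean(axis=1, keepdims=True)
        beta_u_ec = 0.5 * bk * np.sum((mols - r0) ** 2, axis=(1, 2, 3))
        du.append((a - 1.0) * beta_u_ec)
    chain = LambdaChain(lambdas=config.lambdas, du=du)
    est = chain_free_energy(chain, config)
    n_atoms = spec.topology.n_real_atoms
    expected = analytic_f0(config) + 1.5 * (n_atoms - 1) * np.log(a)
    assert abs(est.f - expected) < 3 * est.se, (est.f, expected, est.se)
    assert not any(est.diagnostics["overlap_flags"])


def test_chain_schedule_mismatch_and_validation():
    spec, config = make_config()
    with pytest.raises(ValueError, match="windows"):
        LambdaChain(lambdas=config.lambdas, du=[np.zeros(10)])
    chain = LambdaChain(lambdas=np.array([0.0, 0.5, 1.0]),
                        du=[np.zeros(10)] * 3)
    with pytest.raises(ValueError, match="schedule"):
        chain_free_energy(chain, config)


def test_physical_sampling_fraction():
    assert np.isclose(physical_sampling_fraction(), 4.0 / 23.0)
    assert np.isclose(physical_sampling_fraction(20, 4.0), 4.0 / 23.0)
    with pytest.raises(ValueError):
        physical_sampling_fraction(1)


def test_sampled_fixture_chain_matches_analytic_f():
    """Full ECM pipeline on a small exactly solvable crystal."""
    spec = HarmonicCrystalSpec(n_mol=8, seed=5)
    config = ECMConfig(r0=spec.reference_coords, topology=spec.topology,
                       temperature=spec.temperature)
    rng = np.random.default_rng(6)
    chain = sample_chain_fixture(spec, config, 1200, rng,
                                 n_chains=24, n_burn_sweeps=120, sweeps_per_sample=3)
    est = chain_free_energy(chain, config)
    _, _, f_true = sample_fixture(spec, 1, rng)
    assert est.se < 2.0
    assert abs(est.f - f_true) < 3 * est.se, (est.f, f_true, est.se)
    assert not any(est.diagnostics["overlap_flags"])
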
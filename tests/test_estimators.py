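import numpy as np
import pytest

from latticeflow import estimators
from latticeflow.estimators import (EstimatorError, FreeEnergyEstimate, WorkSet,
                                    bar, bar_v, entropy_per_molecule,
                                    free_energy_ml, generalized_work,
                                    softmax_weights, weighted_running_average)


def gaussian_workset(rng, n, mu_q=0.0, sig_q=1.0, mu_p=1.0, sig_p=1.0, f=0.0):
    """Work values for two 1-D Gaussian states with known Delta f.

    State A ("model"): N(mu_q, sig_q^2), reduced potential -ln q.
    State B ("data"): unnormalized density exp(-(x-mu_p)^2/(2 sig_p^2) - c),
    chosen so that its reduced free energy is exactly ``f``.
    """
    c = f + 0.5 * np.log(2 * np.pi * sig_p ** 2)   # -ln Z_B = f
    xq = rng.normal(mu_q, sig_q, n)
    xp = rng.normal(mu_p, sig_p, n)

    def ln_q(x):
        return -0.5 * ((x - mu_q) / sig_q) ** 2 - 0.5 * np.log(2 * np.pi * sig_q ** 2)

    def beta_u(x):
        return 0.5 * ((x - mu_p) / sig_p) ** 2 + c

    return WorkSet(phi_model=beta_u(xq) + ln_q(xq), phi_data=beta_u(xp) + ln_q(xp))


def test_generalized_work_definition():
    u = np.array([1.0, 2.0])
    lq = np.array([-0.5, 0.5])
    assert np.allclose(generalized_work(2.0, u, lq), [1.5, 4.5])
    with pytest.raises(ValueError):
        generalized_work(1.0, np.zeros(3), np.zeros(2))


def test_workset_cleans_nonfinite_and_errors_beyond_limit():
    phi = np.zeros(10_000)
    phi[0] = np.inf  # 0.01% <= limit
    with pytest.warns(RuntimeWarning, match="non-finite"):
        ws = WorkSet(phi_model=phi, phi_data=np.zeros(100))
    assert ws.n_model == 9_999
    bad = np.zeros(100)
    bad[:5] = np.nan  # 5% > limit
    with pytest.warns(RuntimeWarning), pytest.raises(EstimatorError):
        WorkSet(phi_model=bad, phi_data=np.zeros(100))


def test_bar_perfect_map_exact_with_vanishing_se():
    """Identical states: every work value equals Delta f and the SE vanishes."""
    wf = np.full(500, 3.25)
    wr = np.full(400, -3.25)
    df, se, diag = bar(wf, wr)
    assert np.isclose(df, 3.25, atol=1e-10)
    assert se < 1e-6
    assert diag["ess_forward"] > 100


def test_bar_antisymmetry():
    rng = np.random.default_rng(0)
    ws = gaussian_workset(rng, 2000, f=1.7)
    d1, _, _ = bar(ws.phi_model, -ws.phi_data)
    d2, _, _ = bar(-ws.phi_data, ws.phi_model)
    assert np.isclose(d1, -d2, atol=1e-10)


def test_bar_v_gaussian_oracle_within_three_se():
    """Absolute f of an analytically solvable Gaussian pair, n = 1e4."""
    rng = np.random.default_rng(1)
    f_true = -2.3
    ws = gaussian_workset(rng, 10_000, mu_p=0.8, sig_p=1.3, f=f_true)
    est = bar_v(ws)
    assert est.tag == "BAR_V"
    assert est.se < 0.1
    assert abs(est.f - f_true) < 3 * est.se, (est.f, est.se)


def test_bar_v_shift_invariance_of_normalization():
    """Adding a constant c to ln q shifts f by exactly c (the model side is
    assumed normalized, so the estimate tracks the normalization exactly)."""
    rng = np.random.default_rng(2)
    ws = gaussian_workset(rng, 4000, f=0.4)
    c = 5.0
    ws_shift = WorkSet(phi_model=ws.phi_model + c, phi_data=ws.phi_data + c)
    e0, e1 = bar_v(ws), bar_v(ws_shift)
    assert np.isclose(e1.f - e0.f, c, atol=1e-9)
    assert np.isclose(e1.se, e0.se, rtol=1e-6)


def test_bar_se_matches_replicate_scatter():
    """The analytic SE agrees with the scatter over independent replicates."""
    rng = np.random.default_rng(3)
    fs, ses = [], []
    for _ in range(40):
        ws = gaussian_workset(rng, 1500, mu_p=0.5, f=0.0)
        e = bar_v(ws)
        fs.append(e.f)
        ses.append(e.se)
    emp = np.std(fs, ddof=1)
    ratio = np.mean(ses) / emp
    assert 0.6 < ratio < 1.6, ratio


def test_bar_v_flags_poor_overlap():
    rng = np.random.default_rng(4)
    # nearly disjoint work populations: model side at +40, data side at 0
    ws = WorkSet(phi_model=rng.normal(40.0, 0.5, 500),
                 phi_data=rng.normal(0.0, 0.5, 500))
    with pytest.warns(RuntimeWarning, match="overlap"):
        est = bar_v(ws)
    assert est.se == np.inf
    assert est.diagnostics["overlap_ok"] is False


def test_bar_rejects_disjoint_support():
    with pytest.raises(EstimatorError):
        bar(np.array([]), np.array([1.0]))


def test_free_energy_ml_is_mean_phi():
    phi = np.array([1.0, 2.0, 3.0, 4.0])
    est = free_energy_ml(phi)
    assert np.isclose(est.f, 2.5)
    assert np.isclose(est.se, np.std(phi, ddof=1) / 2.0)
    assert est.tag == "ML"


def test_free_energy_ml_is_lower_bound_in_expectation():
    """E_p[phi] = f - KL(p||q) <= f for a mismatched model."""
    rng = np.random.default_rng(5)
    f_true = 0.9
    ws = gaussian_workset(rng, 20_000, mu_p=1.2, sig_p=0.8, f=f_true)
    est = free_energy_ml(ws.phi_data)
    assert est.f < f_true + 3 * est.se
    # and strictly below for this clearly mismatched pair
    assert est.f < f_true


def test_softmax_weights_concentrate_on_best():
    w = softmax_weights([0.0, 5.0, 3.0])
    assert np.isclose(w.sum(), 1.0)
    assert np.argmax(w) == 1
    # invariance under a common shift
    assert np.allclose(w, softmax_weights([10.0, 15.0, 13.0]))


def test_weighted_running_average_examples():
    f = [1.0, 3.0]
    se = [0.5, 0.1]
    fbar, sebar = weighted_running_average(f, se, [1.0, 1.0])
    assert np.allclose(fbar, [1.0, 2.0])
    assert np.allclose(sebar, [0.5, 0.3])
    fbar, sebar = weighted_running_average(f, se, [1.0, 3.0])
    assert np.allclose(fbar, [1.0, 2.5])
    assert np.allclose(sebar, [0.5, 0.2])
    # rescaling the weights changes nothing
    fbar2, sebar2 = weighted_running_average(f, se, [7.0, 21.0])
    assert np.allclose(fbar, fbar2) and np.allclose(sebar, sebar2)


def test_weighted_running_average_single_and_fallback():
    fbar, sebar = weighted_running_average([2.0], [0.3], [0.7])
    assert fbar[0] == 2.0 and sebar[0] == 0.3
    with pytest.warns(RuntimeWarning, match="uniform"):
        fbar, _ = weighted_running_average([1.0, 3.0], [0.1, 0.1], [0.0, 0.0])
    assert np.allclose(fbar, [1.0, 2.0])
    with pytest.raises(ValueError):
        weighted_running_average([1.0], [0.1], [-1.0])
    with pytest.raises(ValueError):
        weighted_running_average([1.0, 2.0], [0.1], [1.0, 1.0])


def test_entropy_per_molecule():
    assert np.isclose(entropy_per_molecule(100.0, 40.0, 12), 5.0)
    with pytest.raises(ValueError):
        entropy_per_molecule(1.0, 1.0, 0)


def test_free_energy_estimate_rejects_negative_se():
    with pytest.raises(ValueError):
        FreeEnergyEstimate(f=1.0, se=-0.1)
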
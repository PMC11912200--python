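"""Einstein-crystal-method (ECM) reference free energies.

The reduced lattice free energy is assembled as ``f = f0 + sum_i Delta f_i``
along a chain of 20 windows interpolating between a harmonic Einstein crystal
(lambda = 0, free energy f0 known in closed form) and the fully interacting
system (lambda = 1), with each of the 19 neighboring window pairs bridged by
a two-state acceptance-ratio estimate. Standard errors of the pairwise
estimates are summed linearly — a deliberate lower-bound convention rather
than quadrature.

Consistent with the rest of the package, all free energies refer to the
ensemble constrained to a zero oxygen centroid, with orthonormal measure on
that hyperplane; because the Einstein tether is isotropic with a single
scalar spring constant, its constrained free energy remains closed-form. An
alternative three-term bookkeeping (unconstrained Einstein crystal, its
mass-weighted-COM correction, and the physical system's COM volume term) is
provided for cross-checks against the conventional formulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import estimators
from .estimators import FreeEnergyEstimate
from .fixtures import HarmonicCrystalSpec
from .frames import KB, Topology

__all__ = ["ECMConfig", "LambdaChain", "lambda_schedule", "ecm_potential",
           "analytic_f0", "chain_free_energy", "sample_chain_fixture",
           "physical_sampling_fraction"]

#: oxygen-centroid drift (nm) above which a frame is rejected as corrupted
COM_DRIFT_TOL = 1e-6


def lambda_schedule(n: int = 20, exponent: float = 2.0) -> np.ndarray:
    """Deterministic coupling schedule ``1 - (1 - t)**exponent`` on [0, 1].

    ``exponent = 1`` gives even spacing; the default 2 concentrates windows
    near the fully interacting end, where the integrand varies fastest.
    """
    if n < 2:
        raise ValueError("need at least two windows")
    t = np.linspace(0.0, 1.0, n)
    lam = 1.0 - (1.0 - t) ** exponent
    lam[0], lam[-1] = 0.0, 1.0
    return lam


@dataclass
class ECMConfig:
    """Spring constant, schedule and reference structure of the chain.

    ``r0`` is the tether reference (n_atoms, 3) and must have a zero oxygen
    centroid; ``k`` is a single scalar spring (kJ mol^-1 nm^-2) applied to
    every real atom, not mass-weighted.
    """

    r0: np.ndarray
    topology: Topology
    temperature: float
    k: float = 6.0e3
    lambdas: np.ndarray = field(default_factory=lambda_schedule)

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.k <= 0:
            raise ValueError("spring constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.r0.shape != (self.topology.n_real_atoms, 3):
            raise ValueError(
                f"r0 must be ({self.topology.n_real_atoms}, 3) real-atom coordinates")
        lam = self.lambdas
        if lam[0] != 0.0 or lam[-1] != 1.0 or np.any(np.diff(lam) <= 0):
            raise ValueError("lambda schedule must increase strictly from 0 to 1")
        o_idx = self.topology.role_indices("O")
        drift = np.linalg.norm(self.r0[o_idx].mean(axis=0))
        if drift > COM_DRIFT_TOL:
            raise ValueError(f"reference structure oxygen centroid is {drift:.2e} nm from zero")

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def n_windows(self) -> int:
        return self.lambdas.size

    @property
    def normalized_masses(self) -> np.ndarray:
        m = np.array([self.topology.masses[r] for r in self.topology.roles
                      if r != "M"], dtype=float)
        return m / m.sum()


def _check_com(coords: np.ndarray, topology: Topology) -> None:
    o_idx = topology.role_indices("O")
    drift = np.linalg.norm(coords[..., o_idx, :].mean(axis=-2), axis=-1)
    if np.any(drift > COM_DRIFT_TOL):
        raise ValueError(
            f"oxygen-centroid drift up to {drift.max():.2e} nm exceeds {COM_DRIFT_TOL} nm; "
            "re-remove the centroid before evaluating the tether")


def einstein_energy(coords: np.ndarray, config: ECMConfig) -> np.ndarray:
    """Harmonic tether ``(k/2) sum_atoms |r - r0|^2`` in kJ/mol, per frame."""
    d2 = np.sum((coords - config.r0) ** 2, axis=(-2, -1))
    return 0.5 * config.k * d2


def ecm_potential(lam: float, coords: np.ndarray, u_physical: np.ndarray,
                  config: ECMConfig) -> np.ndarray:
    """Interpolated potential ``U_lam = lam U + (1 - lam) U_EC`` in kJ/mol.

    ``coords`` is (..., n_atoms, 3) with a zero oxygen centroid (checked);
    ``u_physical`` is the matching physical potential in kJ/mol.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    coords = np.asarray(coords, dtype=float)
    _check_com(coords, config.topology)
    return lam * np.asarray(u_physical, dtype=float) + (1.0 - lam) * einstein_energy(coords, config)


def analytic_f0(config: ECMConfig, volume: Optional[float] = None,
                convention: str = "constrained") -> float:
    """Closed-form reduced free energy of the lambda = 0 (Einstein) state.

    ``convention="constrained"`` (default): free energy on the oxygen-
    centroid-removed hyperplane with orthonormal measure — the convention the
    chain, the flow and the synthetic fixtures share. Because the tether is
    isotropic and the reference lies in the hyperplane, this is exactly
    ``-(3 (N - 1) / 2) ln(2 pi / (beta k))`` with N the real atom count.

    ``convention="standard"``: the conventional three-term bookkeeping for an
    unconstrained physical system — (i) the free Einstein crystal, (ii) its
    mass-weighted-COM fixing correction involving the normalized masses, and
    (iii) the physical COM volume term ``-ln V`` (requires ``volume`` in nm^3).
    """
    bk = config.beta * config.k
    n_atoms = config.topology.n_real_atoms
    if convention == "constrained":
        return -1.5 * (n_atoms - 1) * np.log(2 * np.pi / bk)
    if convention == "standard":
        if volume is None or volume <= 0:
            raise ValueError("the standard convention requires a positive box volume")
        m = config.normalized_masses
        f_ec_free = -1.5 * n_atoms * np.log(2 * np.pi / bk)
        f_com_fix = 1.5 * np.log(2 * np.pi * np.sum(m ** 2) / bk)
        return f_ec_free + f_com_fix - np.log(volume)
    raise ValueError("convention must be 'constrained' or 'standard'")


@dataclass
class LambdaChain:
    """Per-window samples reduced to the only quantity the bridges need:
    ``du = beta (U - U_EC)`` per sample, per window."""

    lambdas: np.ndarray
    du: List[np.ndarray]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.du) != self.lambdas.size:
            raise ValueError(
                f"chain has {self.lambdas.size} windows but {len(self.du)} sample sets")
        self.du = [np.asarray(d, dtype=float).ravel() for d in self.du]
        if any(d.size == 0 for d in self.du):
            raise ValueError("every window needs at least one sample")


def chain_free_energy(chain: LambdaChain, config: ECMConfig,
                      volume: Optional[float] = None,
                      convention: str = "constrained") -> FreeEnergyEstimate:
    """Assemble ``f = f0 + sum of pairwise bridge estimates``.

    Each neighboring window pair is bridged with the two-state acceptance
    ratio on the cross-evaluated energy differences; the total SE is the
    linear sum of the pairwise SEs (lower-bound convention).
    """
    if not np.array_equal(chain.lambdas, config.lambdas):
        raise ValueError("chain and config lambda schedules differ")
    total = analytic_f0(config, volume=volume, convention=convention)
    se_sum = 0.0
    deltas, ses, flagged = [], [], []
    for i in range(chain.lambdas.size - 1):
        dlam = chain.lambdas[i + 1] - chain.lambdas[i]
        w_f = dlam * chain.du[i]          # u_{i+1} - u_i on window-i samples
        w_r = -dlam * chain.du[i + 1]     # u_i - u_{i+1} on window-(i+1) samples
        df, se, diag = estimators.bar(w_f, w_r)
        ok = min(diag["ess_forward"], diag["ess_reverse"]) > estimators.MIN_ESS
        if not ok:
            warnings.warn(f"poor overlap between windows {i} and {i + 1}", RuntimeWarning)
        deltas.append(df)
        ses.append(se)
        flagged.append(not ok)
        total += df
        se_sum += se
    return FreeEnergyEstimate(
        f=float(total), se=float(se_sum), tag="ECM",
        diagnostics={"pairwise_delta_f": deltas, "pairwise_se": ses,
                     "overlap_flags": flagged, "f0": analytic_f0(config, volume, convention),
                     **chain.diagnostics})


def physical_sampling_fraction(n_windows: int = 20, physical_window_factor: float = 4.0) -> float:
    """Fraction of total sampling effort spent on the physical (lambda = 1)
    window when it is run ``physical_window_factor`` times longer than each of
    the other windows (default: 4 / 23 ~ 17.4%)."""
    if n_windows < 2 or physical_window_factor <= 0:
        raise ValueError("need >= 2 windows and a positive factor")
    return physical_window_factor / (n_windows - 1 + physical_window_factor)


# ---------------------------------------------------------------------------
# Metropolis sampling of the interpolated ensembles on synthetic fixtures
# ---------------------------------------------------------------------------

def _ec_molecule_energy(mols: np.ndarray, r0_mols: np.ndarray, bk: float) -> np.ndarray:
    """Reduced tether energy per molecule; mols is (..., n_mol, 3, 3)."""
    return 0.5 * bk * np.sum((mols - r0_mols) ** 2, axis=(-2, -1))


def _window_energy_pieces(mols, spec: HarmonicCrystalSpec, r0_mols, bk_ec):
    r_o = mols[..., 0, :]
    phys = spec.oxygen_energy(r_o) + spec.hydrogen_energy(
        mols[..., 1, :] - r_o, mols[..., 2, :] - r_o)
    return phys, _ec_molecule_energy(mols, r0_mols, bk_ec)


def sample_chain_fixture(spec: HarmonicCrystalSpec, config: ECMConfig,
                         n_samples: int, rng: np.random.Generator, *,
                         n_chains: int = 32, n_burn_sweeps: int = 200,
                         sweeps_per_sample: int = 5) -> LambdaChain:
    """Sample every window of the chain on a synthetic crystal.

    The lambda = 0 window is drawn exactly from the constrained Gaussian
    tether. Interacting windows use a vectorized Metropolis sampler with two
    move types that both preserve the oxygen-centroid constraint exactly:
    rigid translations of random disjoint molecule pairs with opposite
    displacements, and per-molecule hydrogen block moves (molecule-separable
    energies allow parallel acceptance). Windows are warm-started in
    ascending lambda order; step sizes are tuned during burn-in.
    """
    n = spec.n_mol
    bk_ec = config.beta * config.k
    r0_mols = config.r0.reshape(n, 3, 3)
    sig_ec = 1.0 / np.sqrt(bk_ec)

    def exact_lambda0(n_draw: int) -> np.ndarray:
        mols = r0_mols + rng.standard_normal((n_draw, n, 3, 3)) * sig_ec
        mols[..., 0, :] -= mols[..., 0, :].mean(axis=1, keepdims=True)
        return mols

    per_window = max(1, int(np.ceil(n_samples / n_chains)))
    du: List[np.ndarray] = []
    acc_stats = []

    # window 0 exactly
    mols0 = exact_lambda0(n_chains * per_window)
    phys, ec = _window_energy_pieces(mols0, spec, r0_mols, bk_ec)
    du.append((phys - ec).sum(axis=-1))

    # initial walker states for the Metropolis windows
    state = exact_lambda0(n_chains)
    step_t = 0.5 * sig_ec       # rigid-translation step
    step_h = 0.5 * min(sig_ec, 1.0 / np.sqrt(spec.beta * spec.k_bond))
    for lam in config.lambdas[1:]:
        phys, ec = _window_energy_pieces(state, spec, r0_mols, bk_ec)
        e_mol = lam * phys + (1 - lam) * ec

        def sweep(step_t, step_h):
            nonlocal state, e_mol
            # rigid translations of disjoint molecule pairs with opposite
            # displacements: the oxygen centroid is preserved exactly
            perm = rng.permutation(n)
            pairs = perm[: 2 * (n // 2)].reshape(-1, 2)
            touched = pairs.reshape(-1)
            delta = rng.standard_normal((n_chains, pairs.shape[0], 1, 1, 3)) * step_t
            prop = state.copy()
            prop[:, pairs[:, 0]] += delta[:, :, 0]
            prop[:, pairs[:, 1]] -= delta[:, :, 0]
            sub = prop[:, touched]
            r_o = sub[..., 0, :]
            phys_t = (spec.oxygen_energy_subset(r_o, touched)
                      + spec.hydrogen_energy(sub[..., 1, :] - r_o, sub[..., 2, :] - r_o))
            e_touch = lam * phys_t + (1 - lam) * _ec_molecule_energy(sub, r0_mols[touched], bk_ec)
            e_new = e_touch.reshape(n_chains, -1, 2).sum(axis=-1)
            e_old = e_mol[:, touched].reshape(n_chains, -1, 2).sum(axis=-1)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random((n_chains, pairs.shape[0]))) < (e_old - e_new)
            accept &= np.isfinite(e_new)
            acc_t = accept.mean()
            accept_full = np.zeros((n_chains, n), dtype=bool)
            accept_full[:, pairs[:, 0]] = accept
            accept_full[:, pairs[:, 1]] = accept
            e_prop_full = e_mol.copy()
            e_prop_full[:, touched] = e_touch
            state = np.where(accept_full[..., None, None], prop, state)
            e_mol = np.where(accept_full, e_prop_full, e_mol)

            # hydrogen block moves, all molecules in parallel
            prop_h = state.copy()
            prop_h[..., 1:, :] += rng.standard_normal((n_chains, n, 2, 3)) * step_h
            r_o = prop_h[..., 0, :]
            phys_h = (spec.oxygen_energy(r_o)
                      + spec.hydrogen_energy(prop_h[..., 1, :] - r_o, prop_h[..., 2, :] - r_o))
            ec_h = _ec_molecule_energy(prop_h, r0_mols, bk_ec)
            e_new = lam * phys_h + (1 - lam) * ec_h
            with np.errstate(invalid="ignore"):
                accept_h = np.log(rng.random((n_chains, n))) < (e_mol - e_new)
            accept_h &= np.isfinite(e_new)
            acc_h = accept_h.mean()
            state[accept_h] = prop_h[accept_h]
            e_mol[accept_h] = e_new[accept_h]
            return acc_t, acc_h

        # burn-in with step-size tuning
        for it in range(n_burn_sweeps):
            a_t, a_h = sweep(step_t, step_h)
            if (it + 1) % 20 == 0:
                step_t *= 1.2 if a_t > 0.5 else 0.8
                step_h *= 1.2 if a_h > 0.5 else 0.8
        # production
        samples = np.empty((per_window, n_chains))
        accs = []
        for s in range(per_window):
            for _ in range(sweeps_per_sample):
                accs.append(sweep(step_t, step_h))
            phys, ec = _window_energy_pieces(state, spec, r0_mols, bk_ec)
            samples[s] = (phys - ec).sum(axis=-1)
            # guard against centroid drift from accumulated rounding
            state[..., 0, :] -= state[..., 0, :].mean(axis=1, keepdims=True)
        du.append(samples.ravel())
        accs = np.array(accs)
        acc_stats.append({"lambda": float(lam), "acc_translate": float(accs[:, 0].mean()),
                          "acc_hydrogen": float(accs[:, 1].mean())})

    return LambdaChain(lambdas=config.lambdas, du=du,
                       diagnostics={"acceptance": acc_stats, "n_chains": n_chains,
                                    "samples_per_window": n_chains * per_window})
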
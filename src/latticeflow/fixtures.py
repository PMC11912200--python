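"""Synthetic molecular-crystal ensembles with exactly known free energies.

The fixture emulates locally ergodic NVT samples of a water-like molecular
crystal: oxygen atoms fluctuate harmonically about lattice sites (with the
oxygen centroid constrained to zero), bond lengths and the bond angle are
Gaussian about their means, and each molecule's orientation is concentrated
about a per-site reference orientation via truncated Gaussians in the
hemisphere's hyperspherical angles.

The reduced potential ``betaU`` includes the internal-coordinate Jacobian and
the hemisphere area element, so that the density is an exact product of
(truncated) Gaussians in the internal chart and the configurational partition
function — over the oxygen-centroid-removed hyperplane with orthonormal
measure, the same convention the flow and the Einstein-crystal chain use —
is available in closed form. Molecules are statistically independent apart
from the centroid constraint; anharmonicity and inter-site correlations are
deliberately absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import integrate
from scipy.stats import norm, truncnorm

from . import geometry, representation
from .frames import KB, Ensemble, Topology

__all__ = ["HarmonicCrystalSpec", "sample_fixture", "two_polymorph_fixture", "TwoPolymorphFixture"]


def _grid_dims(n: int) -> Tuple[int, int, int]:
    """Near-cubic factorization of the molecule count."""
    best = None
    for a in range(1, n + 1):
        if n % a:
            continue
        for b in range(a, n + 1):
            if (n // a) % b:
                continue
            c = n // (a * b)
            if c < b:
                continue
            dims = (a, b, c)
            score = c / a
            if best is None or score < best[0]:
                best = (score, dims)
    return best[1]


#: reference hyperspherical angles: centered in every chart range
ROT_MEANS = np.array([np.pi / 4.0, np.pi / 2.0, np.pi])
_ROT_BOUNDS = np.array([[0.0, np.pi / 2], [0.0, np.pi], [0.0, 2 * np.pi]])


@dataclass
class HarmonicCrystalSpec:
    """Parameters of the synthetic crystal.

    Stiffnesses are in kJ mol^-1 nm^-2 (positional, bonds) or
    kJ mol^-1 rad^-2 (angles); geometry follows a TIP4P/Ice-like water:
    O-H bonds of 0.09572 nm and an H-O-H angle of 104.52 degrees (stiffnesses
    are softer than a real force field; see the per-field comments).
    """

    n_mol: int = 16
    temperature: float = 123.15          # kelvin (-150 degC study condition)
    lattice_spacing: float = 0.31        # nm, near the O-O distance in ice
    k_site: float = 1.0e4                # positional spring per oxygen
    d_mean: float = 0.09572              # nm
    # softened relative to a real water force field so that the default
    # 20-window Einstein-crystal chain (spring 6e3 kJ/mol/nm^2) bridges the
    # fixture with comfortable window overlap; still 13 sigma from d = 0
    k_bond: float = 2.0e4
    theta_mean: float = np.deg2rad(104.52)
    k_theta: float = 367.0
    k_rot: float = 100.0                 # per hyperspherical angle
    seed: Optional[int] = None
    site_springs: Optional[np.ndarray] = None  # per-site override of k_site

    def __post_init__(self) -> None:
        for name in ("k_site", "k_bond", "k_theta", "k_rot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_mol < 2:
            raise ValueError("need at least two molecules")
        sigma = 1.0 / np.sqrt(self.beta * self.k_rot)
        margin = min(np.min(ROT_MEANS - _ROT_BOUNDS[:, 0]), np.min(_ROT_BOUNDS[:, 1] - ROT_MEANS))
        if 4.0 * sigma > margin:
            warnings.warn(
                "rotational concentration too low to keep orientations safely "
                "hemisphere-localized (stress-test mode)", RuntimeWarning)

    # -- derived quantities -------------------------------------------------
    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def topology(self) -> Topology:
        return Topology(self.n_mol)

    @property
    def grid(self) -> Tuple[int, int, int]:
        return _grid_dims(self.n_mol)

    @property
    def sites(self) -> np.ndarray:
        """(n_mol, 3) lattice sites with zero centroid."""
        a, b, c = self.grid
        ii, jj, kk = np.meshgrid(np.arange(a), np.arange(b), np.arange(c), indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * self.lattice_spacing
        return pts - pts.mean(axis=0)

    @property
    def box(self) -> np.ndarray:
        return np.diag(np.array(self.grid) * self.lattice_spacing)

    @property
    def bk_site(self) -> np.ndarray:
        k = self.site_springs if self.site_springs is not None else np.full(self.n_mol, self.k_site)
        return self.beta * np.asarray(k, dtype=float)

    @property
    def rot_means(self) -> np.ndarray:
        return ROT_MEANS

    def _modes(self):
        """Per-molecule truncated-Gaussian modes: (mean, beta*k, lower, upper)."""
        b = self.beta
        return [
            (self.d_mean, b * self.k_bond, 0.0, np.inf),
            (self.d_mean, b * self.k_bond, 0.0, np.inf),
            (self.theta_mean, b * self.k_theta, 0.0, np.pi),
            (ROT_MEANS[0], b * self.k_rot, 0.0, np.pi / 2),
            (ROT_MEANS[1], b * self.k_rot, 0.0, np.pi),
            (ROT_MEANS[2], b * self.k_rot, 0.0, 2 * np.pi),
        ]

    @property
    def reference_coords(self) -> np.ndarray:
        """Mean structure (n_atoms, 3): the natural Einstein-crystal tether."""
        q = geometry.hyperspherical_to_quat(np.broadcast_to(ROT_MEANS, (self.n_mol, 3)))
        v1, v2 = representation._vectors_from_internals(
            np.full(self.n_mol, self.d_mean), np.full(self.n_mol, self.d_mean),
            np.full(self.n_mol, self.theta_mean), q)
        r_o = self.sites
        return np.stack([r_o, r_o + v1, r_o + v2], axis=1).reshape(-1, 3)

    # -- free energy ---------------------------------------------------------
    def log_z_oxygen(self) -> float:
        """Log partition function of the centroid-constrained oxygen block
        (orthonormal measure on the 3(n_mol - 1)-dim hyperplane)."""
        n = self.n_mol
        bk = self.bk_site
        if np.allclose(bk, bk[0]):
            return 1.5 * (n - 1) * np.log(2 * np.pi / bk[0])
        # restricted determinant of the precision on the complement of the
        # uniform-translation direction, per spatial component
        v = np.ones((n, 1)) / np.sqrt(n)
        Q, _ = np.linalg.qr(np.eye(n) - v @ v.T)
        B = Q[:, : n - 1]
        sign, logdet = np.linalg.slogdet(B.T @ np.diag(bk) @ B)
        return 1.5 * (n - 1) * np.log(2 * np.pi) - 1.5 * logdet

    def log_z_molecule(self) -> float:
        """Log normalizer of one molecule's six internal modes."""
        total = 0.0
        for mu, bk, a, b in self._modes():
            s = 1.0 / np.sqrt(bk)
            mass = norm.cdf((b - mu) / s) - norm.cdf((a - mu) / s)
            total += 0.5 * np.log(2 * np.pi / bk) + np.log(mass)
        return total

    @property
    def analytic_f(self) -> float:
        """Reduced configurational free energy ``f = -ln Z`` (k_B T units)."""
        return -(self.log_z_oxygen() + self.n_mol * self.log_z_molecule())

    def analytic_mean_potential(self) -> float:
        """Exact ``<betaU>`` (quadratic modes by equipartition; the Jacobian
        and area-element terms by 1-D quadrature over each mode)."""
        mean = 0.5 * (9 * self.n_mol - 3)
        logj = self.n_mol * (
            np.log(8.0)
            + 2 * self._expect(np.log, 0) + 2 * self._expect(np.log, 1)
            + self._expect(lambda x: np.log(np.sin(x)), 2)
            + 2 * self._expect(lambda x: np.log(np.sin(x)), 3)
            + self._expect(lambda x: np.log(np.sin(x)), 4)
        )
        return mean + logj

    def analytic_entropy_per_molecule(self) -> float:
        return (self.analytic_mean_potential() - self.analytic_f) / self.n_mol

    def _expect(self, fn, mode_index: int) -> float:
        mu, bk, a, b = self._modes()[mode_index]
        s = 1.0 / np.sqrt(bk)
        lo, hi = max(a, mu - 10 * s), min(b, mu + 10 * s)
        num, _ = integrate.quad(lambda x: fn(x) * norm.pdf(x, mu, s), lo, hi)
        mass = norm.cdf((b - mu) / s) - norm.cdf((a - mu) / s)
        return num / mass

    # -- energies ------------------------------------------------------------
    def oxygen_energy(self, r_o: np.ndarray) -> np.ndarray:
        """Per-oxygen reduced site energy; ``r_o`` is (..., n_mol, 3)."""
        d2 = np.sum((r_o - self.sites) ** 2, axis=-1)
        return 0.5 * self.bk_site * d2

    def oxygen_energy_subset(self, r_o: np.ndarray, indices: np.ndarray) -> np.ndarray:
        """Site energy of a subset of molecules; ``r_o`` is (..., len(indices), 3)."""
        d2 = np.sum((r_o - self.sites[indices]) ** 2, axis=-1)
        return 0.5 * self.bk_site[indices] * d2

    def hydrogen_energy(self, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
        """Per-molecule reduced energy of the hydrogen block given the two
        bond vectors (..., 3); includes the Jacobian and area-element terms.
        Collinear or degenerate geometries get +inf."""
        d1 = np.linalg.norm(v1, axis=-1)
        d2 = np.linalg.norm(v2, axis=-1)
        bad = (d1 <= 1e-12) | (d2 <= 1e-12)
        d1s, d2s = np.where(bad, 1.0, d1), np.where(bad, 1.0, d2)
        cos_t = np.clip(np.einsum("...x,...x->...", v1, v2) / (d1s * d2s), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sin(theta)
        bad = bad | (sin_t <= 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            u1 = v1 / d1s[..., None]
            e2 = (v2 / d2s[..., None] - cos_t[..., None] * u1) / np.where(bad, 1.0, sin_t)[..., None]
            e3 = np.cross(u1, e2)
            R = np.stack([u1, e2, e3], axis=-1)
            q = geometry.quat_from_matrix(np.where(bad[..., None, None], np.eye(3), R))
            s = geometry.quat_to_hyperspherical(q)
            b = self.beta
            quad = (0.5 * b * self.k_bond * ((d1 - self.d_mean) ** 2 + (d2 - self.d_mean) ** 2)
                    + 0.5 * b * self.k_theta * (theta - self.theta_mean) ** 2
                    + 0.5 * b * self.k_rot * np.sum((s - ROT_MEANS) ** 2, axis=-1))
            logj = np.log(8.0) + 2 * np.log(d1s) + 2 * np.log(d2s) + np.log(np.where(bad, 1.0, sin_t))
            area = geometry.log_area_element(s, clip=1e-150)
        return np.where(bad, np.inf, quad + logj + area)

    def per_molecule_energy(self, coords: np.ndarray) -> np.ndarray:
        """(..., n_mol) reduced energy split by molecule."""
        mols = coords.reshape(coords.shape[:-2] + (self.n_mol, 3, 3))
        r_o = mols[..., 0, :]
        return self.oxygen_energy(r_o) + self.hydrogen_energy(
            mols[..., 1, :] - r_o, mols[..., 2, :] - r_o)

    def beta_potential(self, coords: np.ndarray) -> np.ndarray:
        """Total reduced potential per frame; coords (..., n_atoms, 3)."""
        return self.per_molecule_energy(coords).sum(axis=-1)

    def quadratic_mode_energy(self, coords: np.ndarray) -> np.ndarray:
        """The purely quadratic part of betaU (used by equipartition checks)."""
        mols = coords.reshape(coords.shape[:-2] + (self.n_mol, 3, 3))
        r_o = mols[..., 0, :]
        v1 = mols[..., 1, :] - r_o
        v2 = mols[..., 2, :] - r_o
        d1 = np.linalg.norm(v1, axis=-1)
        d2 = np.linalg.norm(v2, axis=-1)
        cos_t = np.clip(np.einsum("...x,...x->...", v1, v2) / (d1 * d2), -1.0, 1.0)
        theta = np.arccos(cos_t)
        _, _, _, q = representation._internals_from_vectors(v1, v2)
        s = geometry.quat_to_hyperspherical(q)
        b = self.beta
        quad = (0.5 * b * self.k_bond * ((d1 - self.d_mean) ** 2 + (d2 - self.d_mean) ** 2)
                + 0.5 * b * self.k_theta * (theta - self.theta_mean) ** 2
                + 0.5 * b * self.k_rot * np.sum((s - ROT_MEANS) ** 2, axis=-1))
        return (quad + self.oxygen_energy(r_o)).sum(axis=-1)

    def log_density(self, coords: np.ndarray) -> np.ndarray:
        """Exactly normalized log density on the constrained hyperplane."""
        return -self.beta_potential(coords) + self.analytic_f

    # -- sampling ------------------------------------------------------------
    def sample_oxygens(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        var = 1.0 / self.bk_site
        y = self.sites + rng.standard_normal((n_frames, self.n_mol, 3)) * np.sqrt(var)[:, None]
        # exact Gaussian conditioning on a zero centroid
        corr = (var[:, None] / var.sum()) * y.sum(axis=1, keepdims=True)
        return y - corr

    def sample_internal_modes(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        """(n_frames, n_mol, 6): d1, d2, theta, theta0, theta1, theta2."""
        out = np.empty((n_frames, self.n_mol, 6))
        for k, (mu, bk, a, b) in enumerate(self._modes()):
            s = 1.0 / np.sqrt(bk)
            out[..., k] = truncnorm.rvs((a - mu) / s, (b - mu) / s, loc=mu, scale=s,
                                        size=(n_frames, self.n_mol), random_state=rng)
        return out


def sample_fixture(spec: HarmonicCrystalSpec, n_frames: int,
                   rng: Optional[np.random.Generator] = None):
    """Draw independent frames; returns ``(ensemble, betaU, analytic_f)``.

    Frames are exactly Boltzmann-distributed under ``spec.beta_potential`` on
    the oxygen-centroid-removed hyperplane, and ``analytic_f = -ln Z`` of that
    constrained ensemble is known in closed form.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    r_o = spec.sample_oxygens(n_frames, rng)
    modes = spec.sample_internal_modes(n_frames, rng)
    q = geometry.hyperspherical_to_quat(modes[..., 3:6])
    v1, v2 = representation._vectors_from_internals(
        modes[..., 0], modes[..., 1], modes[..., 2], q)
    coords = np.stack([r_o, r_o + v1, r_o + v2], axis=2).reshape(n_frames, -1, 3)
    ens = Ensemble(coords, spec.box, spec.topology, spec.temperature)
    return ens, spec.beta_potential(coords), spec.analytic_f


@dataclass
class TwoPolymorphFixture:
    """Paired synthetic polymorphs with analytic free-energy and entropy gaps."""

    spec_a: HarmonicCrystalSpec
    spec_b: HarmonicCrystalSpec

    def __post_init__(self) -> None:
        if self.spec_a.n_mol != self.spec_b.n_mol:
            raise ValueError("polymorph fixtures must have the same molecule count")

    @property
    def delta_f(self) -> float:
        """Analytic ``f_A - f_B`` in k_B T."""
        return self.spec_a.analytic_f - self.spec_b.analytic_f

    @property
    def delta_s_per_molecule(self) -> float:
        return (self.spec_a.analytic_entropy_per_molecule()
                - self.spec_b.analytic_entropy_per_molecule())

    def sample(self, n_frames: int, rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng() if rng is None else rng
        return (sample_fixture(self.spec_a, n_frames, rng),
                sample_fixture(self.spec_b, n_frames, rng))


def two_polymorph_fixture(spec_a: HarmonicCrystalSpec,
                          spec_b: HarmonicCrystalSpec) -> TwoPolymorphFixture:
    return TwoPolymorphFixture(spec_a, spec_b)
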
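"""Supercell configurations and molecular topology.

Coordinates are stored in nm, temperatures in kelvin. Atom ordering within a
molecule is O, H1, H2 (and optionally a virtual site M); molecules are stored
contiguously. A :class:`Topology` records roles, molecule indices, masses and
virtual-site weights; :class:`SupercellFrame` is one configuration and
:class:`Ensemble` a stack of frames sharing box, topology and temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: gas constant in kJ mol^-1 K^-1 (so that beta = 1 / (KB * T) with energies in kJ/mol)
KB = 0.008314462618

ROLES = ("O", "H1", "H2", "M")

#: TIP4P/Ice-like default masses (amu)
DEFAULT_MASSES = {"O": 15.999, "H1": 1.008, "H2": 1.008, "M": 0.0}


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) + 273.15


@dataclass
class Topology:
    """Molecule count, per-atom roles and virtual-site weights.

    ``virtual_site_weights = (w_O, w_H, w_H)`` define the virtual site as the
    fixed linear combination ``w_O r_O + w_H r_H1 + w_H r_H2``; they are a
    force-field property and must sum to 1.
    """

    n_mol: int
    has_virtual_site: bool = False
    virtual_site_weights: Optional[Sequence[float]] = None
    masses: dict = field(default_factory=lambda: dict(DEFAULT_MASSES))

    def __post_init__(self) -> None:
        if self.n_mol < 1:
            raise ValueError("need at least one molecule")
        if self.virtual_site_weights is not None:
            w = np.asarray(self.virtual_site_weights, dtype=float)
            if w.shape != (3,):
                raise ValueError("virtual-site weights must be 3 scalars (w_O, w_H, w_H)")
            if abs(w.sum() - 1.0) > 1e-10:
                raise ValueError(f"virtual-site weights must sum to 1, got {w.sum()!r}")

    @property
    def atoms_per_mol(self) -> int:
        return 4 if self.has_virtual_site else 3

    @property
    def n_atoms(self) -> int:
        """Number of stored atoms (including virtual sites)."""
        return self.n_mol * self.atoms_per_mol

    @property
    def n_real_atoms(self) -> int:
        """Atoms carrying degrees of freedom (O, H1, H2)."""
        return self.n_mol * 3

    @property
    def roles(self) -> np.ndarray:
        per_mol = ["O", "H1", "H2"] + (["M"] if self.has_virtual_site else [])
        return np.array(per_mol * self.n_mol)

    @property
    def mol_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_mol), self.atoms_per_mol)

    def role_indices(self, role: str) -> np.ndarray:
        offset = {"O": 0, "H1": 1, "H2": 2, "M": 3}[role]
        if role == "M" and not self.has_virtual_site:
            raise ValueError("topology has no virtual sites")
        return offset + self.atoms_per_mol * np.arange(self.n_mol)

    def without_virtual_site(self) -> "Topology":
        return Topology(self.n_mol, has_virtual_site=False,
                        virtual_site_weights=self.virtual_site_weights, masses=self.masses)

    def with_virtual_site(self, weights: Sequence[float]) -> "Topology":
        return Topology(self.n_mol, has_virtual_site=True,
                        virtual_site_weights=weights, masses=self.masses)


def _check_finite(coords: np.ndarray) -> None:
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates in frame")


@dataclass
class SupercellFrame:
    """One supercell configuration (coordinates in nm, fixed NVT box)."""

    coords: np.ndarray
    box: np.ndarray
    topology: Topology
    temperature: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"expected coords of shape {(self.topology.n_atoms, 3)}, got {self.coords.shape}")
        if self.box.shape != (3, 3):
            raise ValueError("box must be 3 lattice vectors (3x3)")
        _check_finite(self.coords)

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)


@dataclass
class Ensemble:
    """A stack of frames sharing box, topology and temperature (NVT)."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray
    topology: Topology
    temperature: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"expected coords of shape (F, {self.topology.n_atoms}, 3), got {self.coords.shape}")
        _check_finite(self.coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def beta(self) -> float:
        return 1.0 / (KB * self.temperature)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.box)))

    def frame(self, i: int) -> SupercellFrame:
        return SupercellFrame(self.coords[i], self.box, self.topology, self.temperature)

    def subset(self, idx) -> "Ensemble":
        return Ensemble(self.coords[idx], self.box, self.topology, self.temperature)
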
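"""Optional MD-engine adapter.

The core package needs only frames and energies; producing them for real ice
polymorphs requires a molecular-dynamics engine, which is an optional
dependency. This module encodes the full simulation protocol as a plain
descriptor so that (a) the protocol is testable arithmetic without an engine
and (b) an engine backend, when present, consumes one unambiguous input.

Protocol summary (rigid 4-site water, NVT production): PME electrostatics
with tolerance 1e-5, real-space cutoff 0.31 nm with a switching function from
0.279 nm, Langevin middle-scheme integrator with 20 ps^-1 friction and a 2 fs
timestep, frames saved every 50 steps (100 fs apart). The production box
comes from an anisotropic NPT pre-equilibration at 1 atm: production starts
from the frame whose box best matches the NPT average. For the Einstein-
crystal chain, the fully interacting window is run 4x longer than each of
the other windows.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .frames import Topology

__all__ = ["MDProtocol", "md_adapter_config", "EngineNotAvailable"]


class EngineNotAvailable(RuntimeError):
    pass


@dataclass
class MDProtocol:
    """Engine-agnostic simulation descriptor (all values explicit)."""

    n_mol: int
    temperature_K: float
    # electrostatics / nonbonded
    pme_tolerance: float = 1e-5
    cutoff_nm: float = 0.31
    switch_nm: float = 0.279
    # integrator
    integrator: str = "langevin-middle"
    friction_per_ps: float = 20.0
    timestep_fs: float = 2.0
    # sampling
    save_stride_steps: int = 50
    production_ns: float = 20.0
    # NPT pre-equilibration
    npt_pressure_atm: float = 1.0
    npt_anisotropic: bool = True
    npt_box_selection: str = "closest-to-average"
    # Einstein-crystal chain
    ecm_n_windows: int = 20
    ecm_physical_window_factor: float = 4.0
    water_model: str = "tip4p/ice"
    rigid_water: bool = True

    @property
    def frame_interval_fs(self) -> float:
        return self.timestep_fs * self.save_stride_steps

    @property
    def n_frames(self) -> int:
        return int(round(self.production_ns * 1e6 / self.frame_interval_fs))

    def to_yaml(self, path: Optional[str] = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path: str) -> "MDProtocol":
        try:
            with open(text_or_path) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, ValueError):
            doc = yaml.safe_load(text_or_path)
        return cls(**doc)


def md_adapter_config(topology: Topology, temperature_K: float,
                      production_ns: Optional[float] = None, **overrides) -> MDProtocol:
    """Build the protocol descriptor for a supercell.

    The default production length is 20 ns (200,000 frames at 100 fs/frame)
    for systems up to 32 molecules and 40 ns for larger supercells.
    """
    if production_ns is None:
        production_ns = 20.0 if topology.n_mol <= 32 else 40.0
    return MDProtocol(n_mol=topology.n_mol, temperature_K=temperature_K,
                      production_ns=production_ns, **overrides)


def build_engine_system(protocol: MDProtocol):
    """Instantiate the descriptor in an MD engine (optional dependency)."""
    try:
        import openmm  # noqa: F401
    except ImportError as exc:
        raise EngineNotAvailable(
            "no MD engine installed: running real-ice simulations requires the "
            "optional 'openmm' dependency (pip install openmm). The rest of the "
            "package — synthetic fixtures, training, estimators, the Einstein-"
            "crystal chain and extrapolation — works without it.") from exc
    raise NotImplementedError(
        "engine backend wiring is intentionally out of scope; consume the "
        "MDProtocol descriptor from your simulation driver")
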
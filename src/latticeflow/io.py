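"""File formats and run configuration.

Conventions: coordinates are stored in nm everywhere inside the package; the
single unit-conversion boundary is at I/O (PDB files are angstroms on disk).
Atom indexing is 0-based internally; frames keep strict file order.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .frames import DEFAULT_MASSES, Ensemble, Topology, celsius_to_kelvin

__all__ = ["write_xyz", "read_xyz", "write_pdb", "read_pdb",
           "write_energies", "read_energies", "save_topology", "load_topology",
           "RunConfig"]

_ROLE_ELEMENT = {"O": "O", "H1": "H", "H2": "H", "M": "M"}


def _elements(topology: Topology) -> list:
    return [_ROLE_ELEMENT[r] for r in topology.roles]


# ---------------------------------------------------------------------------
# XYZ (nm)
# ---------------------------------------------------------------------------

def write_xyz(path: str, ensemble: Ensemble, precision: int = 9) -> None:
    """Plain XYZ in nm; the comment line carries the box diagonal and T."""
    el = _elements(ensemble.topology)
    diag = np.diag(ensemble.box)
    fmt = f"%s %.{precision}f %.{precision}f %.{precision}f\n"
    with open(path, "w") as fh:
        for i in range(len(ensemble)):
            fh.write(f"{ensemble.topology.n_atoms}\n")
            fh.write(f"frame={i} box_nm={diag[0]:.9f},{diag[1]:.9f},{diag[2]:.9f} "
                     f"T_K={ensemble.temperature:.6f}\n")
            for a, (x, y, z) in zip(el, ensemble.coords[i]):
                fh.write(fmt % (a, x, y, z))


def read_xyz(path: str, topology: Topology, box: Optional[np.ndarray] = None,
             temperature: Optional[float] = None) -> Ensemble:
    """Read an XYZ trajectory (nm) against a known topology.

    The box and temperature are parsed from the comment line when present
    (as written by :func:`write_xyz`) and can be overridden by the arguments.
    Atom-count drift, unknown element labels and truncated frames are hard
    errors naming the offending frame.
    """
    expected = _elements(topology)
    n_atoms = topology.n_atoms
    frames = []
    parsed_box = None
    parsed_t = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos, frame_idx = 0, 0
    while pos < len(lines):
        if lines[pos].strip() == "":
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"frame {frame_idx}: malformed atom-count line") from exc
        if count != n_atoms:
            raise ValueError(
                f"frame {frame_idx}: atom count {count} does not match topology ({n_atoms})")
        if pos + 1 + n_atoms >= len(lines) + 1 and pos + 1 + n_atoms > len(lines):
            raise ValueError(f"frame {frame_idx}: truncated (expected {n_atoms} atom lines)")
        comment = lines[pos + 1]
        if frame_idx == 0:
            for tok in comment.split():
                if tok.startswith("box_nm="):
                    parsed_box = np.diag([float(v) for v in tok[7:].split(",")])
                if tok.startswith("T_K="):
                    parsed_t = float(tok[4:])
        body = lines[pos + 2: pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ValueError(f"frame {frame_idx}: truncated (got {len(body)} of {n_atoms} atoms)")
        coords = np.empty((n_atoms, 3))
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"frame {frame_idx}: truncated atom line {a}")
            if parts[0] != expected[a]:
                raise ValueError(
                    f"frame {frame_idx}: unexpected element label {parts[0]!r} at atom {a} "
                    f"(topology expects {expected[a]!r})")
            coords[a] = [float(v) for v in parts[1:4]]
        frames.append(coords)
        pos += 2 + n_atoms
        frame_idx += 1
    if not frames:
        raise ValueError("no frames in file")
    box = box if box is not None else parsed_box
    if box is None:
        raise ValueError("no box information in file or arguments")
    temperature = temperature if temperature is not None else parsed_t
    if temperature is None:
        raise ValueError("no temperature in file or arguments")
    return Ensemble(np.array(frames), np.asarray(box, dtype=float), topology, temperature)


# ---------------------------------------------------------------------------
# minimal PDB (angstrom on disk; nm in memory)
# ---------------------------------------------------------------------------

def write_pdb(path: str, ensemble: Ensemble) -> None:
    """Minimal multi-MODEL PDB writer (fixed-width, angstroms on disk)."""
    el = _elements(ensemble.topology)
    roles = ensemble.topology.roles
    mol = ensemble.topology.mol_index
    a_nm, b_nm, c_nm = np.diag(ensemble.box)
    with open(path, "w") as fh:
        fh.write(f"CRYST1{a_nm * 10:9.3f}{b_nm * 10:9.3f}{c_nm * 10:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for i in range(len(ensemble)):
            fh.write(f"MODEL     {i + 1:4d}\n")
            for a in range(ensemble.topology.n_atoms):
                x, y, z = ensemble.coords[i, a] * 10.0  # nm -> angstrom
                name = {"O": "O", "H1": "H1", "H2": "H2", "M": "MW"}[roles[a]]
                fh.write(f"ATOM  {a + 1:5d} {name:<4s}HOH "
                         f"A{mol[a] + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                         f"{1.00:6.2f}{0.00:6.2f}          {el[a]:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path: str, topology: Topology, temperature: float) -> Ensemble:
    """Read the PDB subset written by :func:`write_pdb` (angstrom -> nm)."""
    n_atoms = topology.n_atoms
    frames = []
    current = []
    box = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = np.diag([float(line[6:15]), float(line[15:24]), float(line[24:33])]) / 10.0
            elif rec in ("ATOM  ", "HETATM"):
                current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            elif rec.startswith("ENDMDL"):
                if len(current) != n_atoms:
                    raise ValueError(
                        f"frame {len(frames)}: {len(current)} atoms, topology expects {n_atoms}")
                frames.append(np.array(current) / 10.0)
                current = []
    if current:
        raise ValueError(f"frame {len(frames)}: truncated (no ENDMDL terminator)")
    if not frames:
        raise ValueError("no frames in file")
    if box is None:
        raise ValueError("missing CRYST1 record")
    return Ensemble(np.array(frames), box, topology, temperature)


# ---------------------------------------------------------------------------
# energies CSV
# ---------------------------------------------------------------------------

def write_energies(path: str, beta_u: np.ndarray) -> None:
    """One reduced potential (k_B T) per frame, aligned with the trajectory."""
    beta_u = np.asarray(beta_u, dtype=float)
    with open(path, "w") as fh:
        fh.write("frame,beta_u\n")
        for i, v in enumerate(beta_u):
            fh.write(f"{i},{v:.12g}\n")


def read_energies(path: str) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:2] != ["frame", "beta_u"]:
            raise ValueError("expected 'frame,beta_u' header")
        rows = [line.strip().split(",") for line in fh if line.strip()]
    idx = np.array([int(r[0]) for r in rows])
    if not np.array_equal(idx, np.arange(len(rows))):
        raise ValueError("frame indices must be 0..n-1 in order")
    return np.array([float(r[1]) for r in rows])


# ---------------------------------------------------------------------------
# topology YAML
# ---------------------------------------------------------------------------

def save_topology(path: str, topology: Topology) -> None:
    doc = {"n_mol": int(topology.n_mol),
           "has_virtual_site": bool(topology.has_virtual_site),
           "masses": {k: float(v) for k, v in topology.masses.items()}}
    if topology.virtual_site_weights is not None:
        doc["virtual_site_weights"] = [float(w) for w in topology.virtual_site_weights]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_topology(path: str) -> Topology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Topology(
        n_mol=int(doc["n_mol"]),
        has_virtual_site=bool(doc.get("has_virtual_site", False)),
        virtual_site_weights=doc.get("virtual_site_weights"),
        masses=doc.get("masses", dict(DEFAULT_MASSES)))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialized into every output
    directory and hash-stamped. Temperatures may be given in Celsius at
    construction time but are stored in kelvin."""

    model_kind: str = "H"
    temperature: float = 123.15       # kelvin
    seed: int = 0
    data_path: Optional[str] = None
    energies_path: Optional[str] = None
    topology_path: Optional[str] = None
    out_dir: Optional[str] = None
    options: dict = field(default_factory=dict)

    @classmethod
    def with_celsius(cls, temperature_celsius: float, **kwargs) -> "RunConfig":
        return cls(temperature=celsius_to_kelvin(temperature_celsius), **kwargs)

    def to_dict(self) -> dict:
        return {"model_kind": self.model_kind, "temperature_K": self.temperature,
                "seed": self.seed, "data_path": self.data_path,
                "energies_path": self.energies_path, "topology_path": self.topology_path,
                "out_dir": self.out_dir, "options": self.options}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("config_hash", None)
        if "temperature_C" in d:
            d["temperature_K"] = celsius_to_kelvin(d.pop("temperature_C"))
        return cls(model_kind=d.get("model_kind", "H"),
                   temperature=float(d.get("temperature_K", 123.15)),
                   seed=int(d.get("seed", 0)), data_path=d.get("data_path"),
                   energies_path=d.get("energies_path"),
                   topology_path=d.get("topology_path"), out_dir=d.get("out_dir"),
                   options=d.get("options", {}))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, out_dir: str) -> str:
        os.makedirs(out_dir, exist_ok=True)
        doc = self.to_dict()
        doc["config_hash"] = self.config_hash()
        path = os.path.join(out_dir, "config.yaml")
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        return path

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
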
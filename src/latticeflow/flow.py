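"""Flow models over crystal supercell configurations.

Two architectures over the same trainable backbone of rational-quadratic
spline coupling layers:

* model ``C``: whitened oxygen coordinates + raw hydrogen Cartesians;
* model ``H``: whitened oxygen coordinates + per-molecule internal
  coordinates (d1, d2, theta) + hemisphere-quaternion hyperspherical angles.

The base distribution is flat: uniform on [-1, 1] per dimension for model C;
for model H, uniform on the q0 >= 0 hemisphere of S^3 per molecule times
uniform intervals for the remaining degrees of freedom. ``log_prob`` returns
the exactly normalized log density ``ln q(r) = ln p0(z) + ln gamma_{r->z}(r)``
with every fixed and trainable layer contributing its exact log-volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import _ad, geometry, representation, splines
from ._ad import Tensor
from .frames import Ensemble, Topology
from .whitening import WhiteningTransform, fit_whitening

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# dimension bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class DimensionSpec:
    """Metadata of the 3(N-1) marginal variables (N = real atom count)."""

    kind: str
    n_mol: int

    def __post_init__(self) -> None:
        if self.kind not in ("C", "H"):
            raise ValueError("model kind must be 'C' or 'H'")
        if self.n_mol < 2:
            raise ValueError("need at least two molecules (whitening drops 3 COM dims)")

    @property
    def n_whitened(self) -> int:
        return 3 * self.n_mol - 3

    @property
    def n_dims(self) -> int:
        return 9 * self.n_mol - 3  # == 3 (N - 1) with N = 3 n_mol real atoms

    @property
    def slice_whitened(self) -> slice:
        return slice(0, self.n_whitened)

    @property
    def slice_internal(self) -> slice:
        # model H bonds/angle block; model C hydrogen Cartesian block
        return slice(self.n_whitened, self.n_whitened + (3 * self.n_mol if self.kind == "H" else 6 * self.n_mol))

    @property
    def slice_rotational(self) -> slice:
        if self.kind != "H":
            raise ValueError("model C has no rotational block")
        return slice(self.n_whitened + 3 * self.n_mol, self.n_dims)

    @property
    def tags(self) -> np.ndarray:
        t = ["whitened_O"] * self.n_whitened
        if self.kind == "C":
            t += ["hydrogen_cartesian"] * (6 * self.n_mol)
        else:
            t += ["bond1", "bond2", "angle"] * self.n_mol
            t += ["theta0", "theta1", "theta2"] * self.n_mol
        return np.array(t)

    @property
    def periodic(self) -> np.ndarray:
        return self.tags == "theta2"

    @property
    def mask_parity(self) -> np.ndarray:
        """Deterministic parity pattern used to partition coupling layers.

        Splits every molecule's degrees of freedom across the two blocks and
        places positional (whitened) and internal/rotational variables of the
        same parity in opposite blocks, so each block conditions on both
        variable families of its complement.
        """
        n = self.n_mol
        parts = [np.arange(self.n_whitened) % 2]
        if self.kind == "C":
            m, k = np.divmod(np.arange(6 * n), 6)
            parts.append((m + k) % 2)
        else:
            m, k = np.divmod(np.arange(3 * n), 3)
            parts.append((m + k) % 2)
            parts.append((m + k + 1) % 2)
        return np.concatenate(parts)


# ---------------------------------------------------------------------------
# fixed layers
# ---------------------------------------------------------------------------

@dataclass
class ShiftScaleLayer:
    """Per-dimension linear map ``z = gain * v + offset`` into the spline range."""

    gain: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.gain <= 0):
            raise ValueError("shift-scale gains must be strictly positive")

    @property
    def log_volume(self) -> float:
        """Per-frame log-volume in the v -> z direction."""
        return float(np.sum(np.log(self.gain)))

    def forward(self, v: np.ndarray) -> np.ndarray:
        return v * self.gain + self.offset

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return (z - self.offset) / self.gain


#: fixed full ranges of the hyperspherical angles (lower, upper)
_ANGLE_RANGES = {"theta0": (0.0, np.pi / 2), "theta1": (0.0, np.pi), "theta2": (0.0, 2 * np.pi)}


def fit_shift_scale(v: np.ndarray, dims: DimensionSpec, margin: float = 0.01) -> ShiftScaleLayer:
    """Fit the shift-scale layer on the entire data set (train + validation).

    Data-driven dimensions use the observed min/max extended by ``margin``
    (fraction of the span) on each side; the hyperspherical angles use their
    fixed full ranges so the model can represent every rotation.
    """
    tags = dims.tags
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    if np.any(span <= 0):
        raise ValueError("degenerate marginal with zero span")
    lo = lo - margin * span
    hi = hi + margin * span
    for tag, (a, b) in _ANGLE_RANGES.items():
        sel = tags == tag
        lo[sel], hi[sel] = a, b
    gain = 2.0 / (hi - lo)
    offset = -1.0 - gain * lo
    return ShiftScaleLayer(gain=gain, offset=offset)


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------

class MLP:
    """Two-hidden-layer perceptron conditioner; final layer zero-initialized
    so freshly built couplings are exactly the identity."""

    def __init__(self, n_in: int, n_out: int, hidden: int, rng: np.random.Generator):
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        sizes = [n_in, hidden, hidden, n_out]
        for i in range(3):
            w = rng.standard_normal((sizes[i], sizes[i + 1])) / np.sqrt(sizes[i])
            if i == 2:
                w = np.zeros_like(w)
            self.weights.append(w)
            self.biases.append(np.zeros(sizes[i + 1]))

    def parameters(self) -> List[np.ndarray]:
        return self.weights + self.biases

    def set_parameters(self, params: List[np.ndarray]) -> None:
        self.weights = [np.asarray(p) for p in params[:3]]
        self.biases = [np.asarray(p) for p in params[3:]]

    def forward_ad(self, x: Tensor, params: List[Tensor]) -> Tensor:
        ws, bs = params[:3], params[3:]
        h = x
        for i in range(3):
            h = _ad.matmul(h, ws[i]) + bs[i]
            if i < 2:
                h = _ad.tanh(h)
        return h

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        h = x
        for i in range(3):
            h = h @ self.weights[i] + self.biases[i]
            if i < 2:
                h = np.tanh(h)
        return h


class SplineCoupling:
    """One coupling layer: transforms the masked block elementwise with
    monotone rational-quadratic splines conditioned on the complement."""

    def __init__(self, transform_mask: np.ndarray, periodic: np.ndarray,
                 n_bins: int, hidden: int, rng: np.random.Generator):
        self.transform_mask = np.asarray(transform_mask, dtype=bool)
        self.t_idx = np.nonzero(self.transform_mask)[0]
        self.c_idx = np.nonzero(~self.transform_mask)[0]
        if self.t_idx.size == 0 or self.c_idx.size == 0:
            raise ValueError("coupling mask must split the dimensions into two nonempty blocks")
        self.periodic_t = np.asarray(periodic, dtype=bool)[self.t_idx]
        self.n_bins = n_bins
        self.mlp = MLP(self.c_idx.size, self.t_idx.size * splines.n_raw_params(n_bins), hidden, rng)
        # output column order of [transformed | conditioning] -> original order
        order = np.concatenate([self.t_idx, self.c_idx])
        self.unpermute = np.argsort(order)

    def _raw_np(self, xc: np.ndarray) -> np.ndarray:
        raw = self.mlp.forward_np(xc)
        return raw.reshape(xc.shape[0], self.t_idx.size, splines.n_raw_params(self.n_bins))

    def forward_ad(self, x: Tensor, params: List[Tensor]):
        xc = x[:, self.c_idx]
        xt = x[:, self.t_idx]
        raw = self.mlp.forward_ad(xc, params)
        raw = raw.reshape(raw.shape[0], self.t_idx.size, splines.n_raw_params(self.n_bins))
        yt, ld = splines.forward(xt, raw, self.n_bins, self.periodic_t)
        y = _ad.concat([yt, xc], axis=-1)[:, self.unpermute]
        return y, ld.sum(axis=1)

    def forward_np(self, x: np.ndarray):
        xc = x[:, self.c_idx]
        yt, ld = splines.forward_np(x[:, self.t_idx], self._raw_np(xc), self.n_bins, self.periodic_t)
        y = np.concatenate([yt, xc], axis=-1)[:, self.unpermute]
        return y, ld.sum(axis=1)

    def inverse_np(self, y: np.ndarray):
        """Returns ``(x, logdet)`` with logdet still in the x -> y direction."""
        yc = y[:, self.c_idx]
        xt, ld = splines.inverse(y[:, self.t_idx], self._raw_np(yc), self.n_bins, self.periodic_t)
        x = np.concatenate([xt, yc], axis=-1)[:, self.unpermute]
        return x, ld.sum(axis=1)

    def parameters(self) -> List[np.ndarray]:
        return self.mlp.parameters()


# ---------------------------------------------------------------------------
# base densities
# ---------------------------------------------------------------------------

def base_log_density(kind: str, n_mol: int) -> float:
    """Constant log base density.

    Model C: uniform on [-1, 1] per marginal, ``-3(N - 1) ln 2``.
    Model H: uniform on the q0 >= 0 hemisphere of S^3 per molecule (surface
    area pi^2) times [-1, 1] intervals for the 6 n_mol - 3 nonrotational
    dimensions: ``-n_mol ln(pi^2) - (6 n_mol - 3) ln 2``.
    """
    d = 9 * n_mol - 3
    if kind == "C":
        return -d * LN2
    if kind == "H":
        return float(-n_mol * np.log(np.pi ** 2) - (6 * n_mol - 3) * LN2)
    raise ValueError("model kind must be 'C' or 'H'")


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class FlowModel:
    kind: str
    topology: Topology
    temperature: float
    dims: DimensionSpec
    whitening: WhiteningTransform
    shift_scale: ShiftScaleLayer
    couplings: List[SplineCoupling]
    rotation_offsets: Optional[np.ndarray] = None  # (n_mol, 4), model H only
    n_bins: int = splines.N_BINS_DEFAULT
    out_of_domain_count: int = field(default=0, compare=False)

    # -- fixed representation chain -------------------------------------
    def preprocess(self, coords: np.ndarray):
        """Cartesian frames -> pre-coupling variables.

        Returns ``(x, fixed_logvol)`` where ``x`` is (F, D) in the spline
        working range and ``fixed_logvol`` (F,) is the summed log-volume of
        every fixed layer in the configuration -> base direction.
        """
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        topo = self.topology
        if topo.has_virtual_site:
            mols = coords.reshape(coords.shape[0], topo.n_mol, 4, 3)[:, :, :3]
            coords = mols.reshape(coords.shape[0], -1, 3)
            topo = topo.without_virtual_site()
        com = representation.oxygen_centroid(coords, topo)
        coords = coords - com[:, None, :]

        F = coords.shape[0]
        fixed = np.zeros(F)
        mols = coords.reshape(F, topo.n_mol, 3, 3)
        o_flat = mols[:, :, 0].reshape(F, -1)
        y_o, lv_w = self.whitening.whiten(o_flat)
        fixed += lv_w
        if self.kind == "C":
            hyd = mols[:, :, 1:].reshape(F, -1)
            v = np.concatenate([y_o, hyd], axis=1)
        else:
            r_o, d1, d2, th, q, lv_int = representation.molecules_to_internal_batch(
                coords, topo)
            fixed += lv_int
            q = representation.apply_rotation_offsets(q, self.rotation_offsets)
            s, lv_area = representation.quaternion_to_hyperspherical(q)
            fixed += lv_area.sum(axis=-1)
            internal = np.stack([d1, d2, th], axis=-1).reshape(F, -1)
            v = np.concatenate([y_o, internal, s.reshape(F, -1)], axis=1)
        x = self.shift_scale.forward(v)
        fixed += self.shift_scale.log_volume
        return x, fixed

    def postprocess(self, x: np.ndarray):
        """Inverse of :func:`preprocess`; returns ``(coords, fixed_logvol)``
        with the log-volume still reported in the configuration -> base
        direction (so it can be summed with forward contributions)."""
        F = x.shape[0]
        topo = self.topology.without_virtual_site() if self.topology.has_virtual_site else self.topology
        v = self.shift_scale.inverse(x)
        fixed = np.full(F, self.shift_scale.log_volume)
        d = self.dims
        o_flat, lv_w = self.whitening.unwhiten(v[:, d.slice_whitened])
        fixed += -lv_w  # report in the to-base direction
        r_o = o_flat.reshape(F, topo.n_mol, 3)
        if self.kind == "C":
            hyd = v[:, d.slice_internal].reshape(F, topo.n_mol, 2, 3)
            mols = np.concatenate([r_o[:, :, None, :], hyd], axis=2)
            coords = mols.reshape(F, -1, 3)
        else:
            internal = v[:, d.slice_internal].reshape(F, topo.n_mol, 3)
            s = v[:, d.slice_rotational].reshape(F, topo.n_mol, 3)
            q, lv_area = representation.hyperspherical_to_quaternion(s)
            fixed += -lv_area.sum(axis=-1)
            q = representation.invert_rotation_offsets(q, self.rotation_offsets)
            coords, lv_int = representation.internal_to_molecules_batch(
                r_o, internal[..., 0], internal[..., 1], internal[..., 2], q)
            fixed += -lv_int
        if self.topology.has_virtual_site:
            w = np.asarray(self.topology.virtual_site_weights, dtype=float)
            mols = coords.reshape(F, topo.n_mol, 3, 3)
            rm = np.einsum("fmkx,k->fmx", mols, w)
            coords = np.concatenate([mols, rm[:, :, None, :]], axis=2).reshape(F, -1, 3)
        return coords, fixed

    # -- trainable chain -------------------------------------------------
    def coupling_parameters(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for c in self.couplings:
            out.extend(c.parameters())
        return out

    def set_coupling_parameters(self, params: List[np.ndarray]) -> None:
        i = 0
        for c in self.couplings:
            c.mlp.set_parameters(params[i:i + 6])
            i += 6

    def couplings_forward_ad(self, x: Tensor, params: List[Tensor]):
        ld = Tensor(np.zeros(x.shape[0]))
        z = x
        i = 0
        for c in self.couplings:
            z, l = c.forward_ad(z, params[i:i + 6])
            i += 6
            ld = ld + l
        return z, ld

    def couplings_forward_np(self, x: np.ndarray):
        ld = np.zeros(x.shape[0])
        z = x
        for c in self.couplings:
            z, l = c.forward_np(z)
            ld += l
        return z, ld

    def couplings_inverse_np(self, z: np.ndarray):
        ld = np.zeros(z.shape[0])
        x = z
        for c in reversed(self.couplings):
            x, l = c.inverse_np(x)
            ld += l
        return x, ld

    # -- densities --------------------------------------------------------
    def base_logpdf_z(self, z: np.ndarray) -> np.ndarray:
        """Log density of the flat base expressed in the z coordinates.

        Equals :func:`base_log_density` plus, for model H, the hemisphere
        area element of the output-side angles (the base is uniform on the
        hemisphere, not in the angle chart). Points outside the working
        interval are clamped and counted in ``out_of_domain_count``.
        """
        F = z.shape[0]
        out = np.sum((z < splines.LEFT - 1e-12) | (z > splines.RIGHT + 1e-12))
        self.out_of_domain_count += int(out)
        if self.kind == "C":
            return np.full(F, -self.dims.n_dims * LN2)
        logp = np.full(F, -(6 * self.dims.n_mol - 3) * LN2 + self.dims.n_mol * np.log(np.pi / 8.0))
        z_rot = np.clip(z[:, self.dims.slice_rotational], splines.LEFT, splines.RIGHT)
        gain = self.shift_scale.gain[self.dims.slice_rotational]
        offset = self.shift_scale.offset[self.dims.slice_rotational]
        s = ((z_rot - offset) / gain).reshape(F, self.dims.n_mol, 3)
        logp += geometry.log_area_element(s).sum(axis=-1)
        return logp

    def base_logpdf_ad(self, z: Tensor) -> Tensor:
        """Differentiable mirror of :func:`base_logpdf_z` (model H's area
        element depends on the coupling outputs, so gradients flow through)."""
        F = z.shape[0]
        if self.kind == "C":
            return Tensor(np.full(F, -self.dims.n_dims * LN2))
        const = -(6 * self.dims.n_mol - 3) * LN2 + self.dims.n_mol * np.log(np.pi / 8.0)
        sl = self.dims.slice_rotational
        z_rot = z[:, sl]
        inside = (z_rot.data >= splines.LEFT) & (z_rot.data <= splines.RIGHT)
        z_rot = _ad.where(inside, z_rot, Tensor(np.clip(z_rot.data, splines.LEFT, splines.RIGHT)))
        gain = self.shift_scale.gain[sl]
        offset = self.shift_scale.offset[sl]
        s = (z_rot - offset) * (1.0 / gain)
        sn = _ad.sin(s)
        clipped = sn.data < geometry.AREA_CLIP
        sn = _ad.where(clipped, Tensor(np.full_like(sn.data, geometry.AREA_CLIP)), sn)
        # area-element exponents per hyperspherical angle: sin^2(t0) sin(t1)
        w = np.tile([2.0, 1.0, 0.0], self.dims.n_mol)
        return (_ad.log(sn) * w).sum(axis=1) + const

    def log_prob(self, coords: np.ndarray) -> np.ndarray:
        """Exactly normalized ``ln q(r)`` per frame."""
        x, fixed = self.preprocess(coords)
        z, ld = self.couplings_forward_np(x)
        return self.base_logpdf_z(z) + fixed + ld

    def sample(self, n: int, rng: np.random.Generator):
        """Draw ``n`` frames from the model; returns ``(coords, ln_q)``."""
        d = self.dims
        z = rng.uniform(splines.LEFT, splines.RIGHT, size=(n, d.n_dims))
        if self.kind == "H":
            q = geometry.random_hemisphere_quat(rng, (n, d.n_mol))
            s = geometry.quat_to_hyperspherical(q).reshape(n, -1)
            sl = d.slice_rotational
            z[:, sl] = self.shift_scale.gain[sl] * s + self.shift_scale.offset[sl]
        ln_base = self.base_logpdf_z(z)
        x, ld = self.couplings_inverse_np(z)
        coords, fixed = self.postprocess(x)
        return coords, ln_base + fixed + ld

    # -- diagnostics ------------------------------------------------------
    def roundtrip_report(self, coords: np.ndarray, coord_tol: float = 1e-5,
                         logvol_tol: float = 1e-6) -> dict:
        """Inversion accuracy in both directions on the given frames."""
        coords = np.asarray(coords, dtype=float)
        x, fixed_f = self.preprocess(coords)
        z, ld_f = self.couplings_forward_np(x)
        x2, ld_i = self.couplings_inverse_np(z)
        coords2, fixed_i = self.postprocess(x2)
        ref = coords
        if self.topology.has_virtual_site:
            # compare real atoms only; virtual sites are reconstructed exactly
            sel = self.topology.roles != "M"
            ref, coords2 = coords[:, sel], coords2[:, sel]
        # the oxygen COM shift applied in preprocess is part of data cleaning,
        # not of the bijection; compare after removing it from the reference
        topo = self.topology.without_virtual_site() if self.topology.has_virtual_site else self.topology
        ref = ref - representation.oxygen_centroid(ref, topo)[:, None, :]
        err = np.linalg.norm(ref - coords2, axis=-1)
        lv_err = np.abs((fixed_f + ld_f) - (fixed_i + ld_i))
        return {
            "max_coord_error": float(err.max()),
            "mean_coord_error": float(err.mean()),
            "max_logvol_error": float(lv_err.max()),
            "mean_logvol_error": float(lv_err.mean()),
            "coord_ok": bool(err.max() < coord_tol),
            "logvol_ok": bool(lv_err.max() < logvol_tol),
            "n_frames": int(coords.shape[0]),
        }


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

DEFAULT_N_LAYERS = {"H": 4, "C": 8}


def build_model(kind: str, topology: Topology, whitening: WhiteningTransform,
                shift_scale: ShiftScaleLayer, n_layers: Optional[int] = None, *,
                temperature: float, rotation_offsets: Optional[np.ndarray] = None,
                n_bins: int = splines.N_BINS_DEFAULT, hidden: int = 128,
                seed: int = 0) -> FlowModel:
    """Assemble a flow model from already-fitted fixed layers."""
    dims = DimensionSpec(kind, topology.n_mol)
    if whitening.n_retained != dims.n_whitened:
        raise ValueError(
            f"whitening retains {whitening.n_retained} dims, topology implies {dims.n_whitened}")
    if shift_scale.gain.shape != (dims.n_dims,):
        raise ValueError("shift-scale dimension mismatch")
    if kind == "H" and rotation_offsets is None:
        raise ValueError("model H requires per-molecule rotation offsets")
    n_layers = DEFAULT_N_LAYERS[kind] if n_layers is None else int(n_layers)
    rng = np.random.default_rng(seed)
    parity = dims.mask_parity
    periodic = dims.periodic
    couplings = [
        SplineCoupling(parity == (layer % 2), periodic, n_bins, hidden, rng)
        for layer in range(n_layers)
    ]
    return FlowModel(kind=kind, topology=topology, temperature=temperature, dims=dims,
                     whitening=whitening, shift_scale=shift_scale, couplings=couplings,
                     rotation_offsets=rotation_offsets, n_bins=n_bins)


def initialize_from_data(kind: str, data: Ensemble, n_layers: Optional[int] = None, *,
                         n_bins: int = splines.N_BINS_DEFAULT, hidden: int = 128,
                         seed: int = 0, margin: float = 0.01) -> FlowModel:
    """Fit whitening, shift-scale and (model H) rotation offsets on the entire
    data set and build the flow with identity-initialized couplings."""
    topo = data.topology.without_virtual_site() if data.topology.has_virtual_site else data.topology
    dims = DimensionSpec(kind, topo.n_mol)
    coords = data.coords
    if data.topology.has_virtual_site:
        coords = coords.reshape(len(data), topo.n_mol, 4, 3)[:, :, :3].reshape(len(data), -1, 3)
    coords = coords - representation.oxygen_centroid(coords, topo)[:, None, :]
    F = coords.shape[0]
    mols = coords.reshape(F, topo.n_mol, 3, 3)
    whit = fit_whitening(mols[:, :, 0].reshape(F, -1))
    y_o, _ = whit.whiten(mols[:, :, 0].reshape(F, -1))
    offsets = None
    if kind == "C":
        v = np.concatenate([y_o, mols[:, :, 1:].reshape(F, -1)], axis=1)
    else:
        _, d1, d2, th, q, _ = representation.molecules_to_internal_batch(coords, topo)
        offsets = representation.align_reference_rotations(q)
        q = representation.apply_rotation_offsets(q, offsets)
        s, _ = representation.quaternion_to_hyperspherical(q)
        internal = np.stack([d1, d2, th], axis=-1).reshape(F, -1)
        v = np.concatenate([y_o, internal, s.reshape(F, -1)], axis=1)
    ss = fit_shift_scale(v, dims, margin=margin)
    return build_model(kind, data.topology, whit, ss, n_layers, temperature=data.temperature,
                       rotation_offsets=offsets, n_bins=n_bins, hidden=hidden, seed=seed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: FlowModel, path: str) -> None:
    arrays = {
        "whitening_mean": model.whitening.mean,
        "whitening_basis": model.whitening.basis,
        "whitening_eigenvalues": model.whitening.eigenvalues,
        "gain": model.shift_scale.gain,
        "offset": model.shift_scale.offset,
    }
    if model.rotation_offsets is not None:
        arrays["rotation_offsets"] = model.rotation_offsets
    for i, p in enumerate(model.coupling_parameters()):
        arrays[f"param_{i}"] = p
    meta = np.array([
        ord(model.kind), model.topology.n_mol, int(model.topology.has_virtual_site),
        len(model.couplings), model.n_bins, model.temperature,
    ])
    arrays["meta"] = meta
    if model.topology.has_virtual_site:
        arrays["vs_weights"] = np.asarray(model.topology.virtual_site_weights, dtype=float)
    np.savez(path, **arrays)


def load_model(path: str) -> FlowModel:
    data = np.load(path)
    meta = data["meta"]
    kind = chr(int(meta[0]))
    n_mol = int(meta[1])
    has_vs = bool(meta[2])
    n_layers, n_bins, temperature = int(meta[3]), int(meta[4]), float(meta[5])
    topo = Topology(n_mol, has_virtual_site=has_vs,
                    virtual_site_weights=data["vs_weights"] if has_vs else None)
    whit = WhiteningTransform(data["whitening_mean"], data["whitening_basis"],
                              data["whitening_eigenvalues"])
    ss = ShiftScaleLayer(data["gain"], data["offset"])
    offsets = data["rotation_offsets"] if "rotation_offsets" in data else None
    hidden = None
    # infer hidden width from the first coupling's first weight matrix
    hidden = data["param_0"].shape[1]
    model = build_model(kind, topo, whit, ss, n_layers, temperature=temperature,
                        rotation_offsets=offsets, n_bins=n_bins, hidden=hidden)
    params = [data[f"param_{i}"] for i in range(6 * n_layers)]
    model.set_coupling_parameters(params)
    return model
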
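"""PCA whitening of centered oxygen coordinates.

Removing the oxygen center of mass confines the 3 n_mol oxygen coordinates to
a 3(n_mol - 1)-dimensional hyperplane. The whitening layer removes exactly
those 3 null directions and rescales the retained eigendirections to unit
variance, contributing an exact, constant log-volume of
``-(1/2) sum_j ln(lambda_j)`` in the whitening direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: eigenvalues below NULL_REL * lambda_max count as null directions
NULL_REL = 1e-10


@dataclass
class WhiteningTransform:
    """Frozen PCA whitening: mean, orthonormal basis of retained directions
    and their (descending) covariance eigenvalues in nm^2."""

    mean: np.ndarray        # (3 n_mol,)
    basis: np.ndarray       # (3 n_mol, 3 n_mol - 3), orthonormal columns
    eigenvalues: np.ndarray  # (3 n_mol - 3,), descending, all > 0

    @property
    def n_retained(self) -> int:
        return self.basis.shape[1]

    @property
    def log_volume_whiten(self) -> float:
        """Per-frame log-volume of the whitening direction."""
        return float(-0.5 * np.sum(np.log(self.eigenvalues)))

    def whiten(self, x: np.ndarray):
        """Project onto retained directions and scale to unit variance.

        Returns ``(y, logvol)`` with the constant whitening log-volume.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.mean.shape[0]:
            raise ValueError(f"dimension mismatch: got {x.shape[-1]}, expected {self.mean.shape[0]}")
        y = (x - self.mean) @ self.basis / np.sqrt(self.eigenvalues)
        return y, self.log_volume_whiten

    def unwhiten(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if y.shape[-1] != self.n_retained:
            raise ValueError(f"dimension mismatch: got {y.shape[-1]}, expected {self.n_retained}")
        x = (y * np.sqrt(self.eigenvalues)) @ self.basis.T + self.mean
        return x, -self.log_volume_whiten

    def to_dict(self) -> dict:
        return {"mean": self.mean, "basis": self.basis, "eigenvalues": self.eigenvalues}

    @classmethod
    def from_dict(cls, d: dict) -> "WhiteningTransform":
        return cls(np.asarray(d["mean"]), np.asarray(d["basis"]), np.asarray(d["eigenvalues"]))


def fit_whitening(oxygen_coords: np.ndarray) -> WhiteningTransform:
    """Fit the whitening transform on the entire data set (train + validation).

    Parameters
    ----------
    oxygen_coords : (n_frames, 3 n_mol) or (n_frames, n_mol, 3)
        COM-removed oxygen coordinates of every available frame.

    Exactly three eigenvalues of the covariance must be null (relative
    threshold 1e-10): fewer means the input was not COM-centered, more means
    the data are degenerate (e.g. a single molecule). Either case is a hard
    error, protecting the 3(n_mol - 1)-dimensional contract.
    """
    x = np.asarray(oxygen_coords, dtype=float)
    if x.ndim == 3:
        x = x.reshape(x.shape[0], -1)
    if x.ndim != 2:
        raise ValueError("expected (n_frames, 3 n_mol) oxygen coordinates")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / x.shape[0]
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    lam_max = eigval[-1]
    if lam_max <= 0:
        raise ValueError("degenerate data: covariance has no positive eigenvalue")
    null = eigval < NULL_REL * lam_max
    if int(null.sum()) != 3:
        raise ValueError(
            f"expected exactly 3 null covariance directions (COM-removed data), found {int(null.sum())}")
    keep = slice(3, None)
    eigval, eigvec = eigval[keep][::-1], eigvec[:, keep][:, ::-1]  # descending
    return WhiteningTransform(mean=mean, basis=np.ascontiguousarray(eigvec),
                              eigenvalues=np.ascontiguousarray(eigval))
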
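"""Extrapolation of lattice free-energy differences to the thermodynamic limit.

Finite supercells bias lattice free-energy differences with a leading 1/n_mol
term, so the infinite-system value is read off as the intercept of an
ordinary least-squares fit of Delta f against 1/n_mol. The fit is deliberately
unweighted; per-point standard errors are propagated through the fixed OLS
coefficients to give the intercept's standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["ExtrapolationResult", "extrapolate"]


@dataclass
class ExtrapolationResult:
    intercept: float        # thermodynamic-limit Delta f
    intercept_se: float
    slope: float            # coefficient of 1/n_mol
    slope_se: float
    n_mol: np.ndarray
    fitted: np.ndarray      # fitted values at the input system sizes

    def predict(self, n_mol) -> np.ndarray:
        return self.intercept + self.slope / np.asarray(n_mol, dtype=float)


def extrapolate(n_mol: Sequence[float], delta_f: Sequence[float],
                se: Optional[Sequence[float]] = None) -> ExtrapolationResult:
    """Unweighted OLS of ``delta_f`` against ``1 / n_mol``.

    Parameters
    ----------
    n_mol : system sizes (at least two distinct values)
    delta_f : free-energy differences in k_B T
    se : optional per-point standard errors; propagated linearly through the
        OLS coefficients (they do not influence the fit itself)
    """
    n = np.asarray(n_mol, dtype=float)
    y = np.asarray(delta_f, dtype=float)
    if n.shape != y.shape or n.ndim != 1 or n.size < 2:
        raise ValueError("need >= 2 aligned (n_mol, delta_f) points")
    if np.any(n <= 0):
        raise ValueError("system sizes must be positive")
    x = 1.0 / n
    if np.ptp(x) == 0:
        raise ValueError("need at least two distinct system sizes")
    A = np.stack([np.ones_like(x), x], axis=1)
    # fixed linear estimator: coef = C y with C = (A^T A)^-1 A^T
    C = np.linalg.solve(A.T @ A, A.T)
    intercept, slope = C @ y
    if se is not None:
        s = np.asarray(se, dtype=float)
        if s.shape != y.shape or np.any(s < 0):
            raise ValueError("standard errors must align with delta_f and be >= 0")
        var = C ** 2 @ s ** 2
        intercept_se, slope_se = np.sqrt(var)
    else:
        intercept_se = slope_se = float("nan")
    fitted = A @ np.array([intercept, slope])
    return ExtrapolationResult(intercept=float(intercept), intercept_se=float(intercept_se),
                               slope=float(slope), slope_se=float(slope_se),
                               n_mol=n, fitted=fitted)
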
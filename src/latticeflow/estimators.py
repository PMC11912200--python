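"""Free-energy estimators for targeted reweighting.

The central object is the generalized work ``phi(r) = beta U(r) + ln q(r)``
evaluated both on data frames (samples of the physical Boltzmann density p)
and on model-generated samples (of the normalized flow density q). A
two-state Bennett acceptance-ratio (BAR) estimate between those two
populations yields the absolute reduced free energy ``f = -ln Z`` of the
physical ensemble, since the model side is normalized and therefore has free
energy zero.

Estimates recorded along a training run are combined by a cumulative weighted
running average whose weights are a softmax over the ML-side estimates
``f_ML = <phi>``: early (badly trained) and late (overfit) evaluations have
lower f_ML and are down-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "EstimatorError", "WorkSet", "FreeEnergyEstimate",
    "generalized_work", "bar", "bar_v", "free_energy_ml",
    "softmax_weights", "weighted_running_average", "entropy_per_molecule",
]

#: runs excluding more than this fraction of non-finite work values fail
MAX_EXCLUDED_FRACTION = 1e-3
#: minimum per-side effective sample size before the SE is meaningful
MIN_ESS = 10.0


class EstimatorError(RuntimeError):
    pass


@dataclass
class FreeEnergyEstimate:
    """A reduced free energy (k_B T units) with its standard error."""

    f: float
    se: float
    tag: str = ""                      # "BAR_V" | "ML" | "ECM" | ...
    index: Optional[int] = None        # evaluation index along a training run
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.se >= 0):  # also rejects NaN
            raise ValueError("standard error must be >= 0")


def generalized_work(beta: float, u: np.ndarray, log_q: np.ndarray) -> np.ndarray:
    """``phi = beta*U + ln q`` elementwise; arrays must be aligned."""
    u = np.asarray(u, dtype=float)
    log_q = np.asarray(log_q, dtype=float)
    if u.shape != log_q.shape:
        raise ValueError(f"length mismatch: U has shape {u.shape}, ln q has {log_q.shape}")
    return beta * u + log_q


def _clean(phi: np.ndarray, label: str) -> Tuple[np.ndarray, float]:
    phi = np.asarray(phi, dtype=float).ravel()
    if phi.size == 0:
        raise EstimatorError(f"{label} work values are empty")
    ok = np.isfinite(phi)
    frac = 1.0 - ok.mean()
    if frac > 0:
        warnings.warn(f"excluding {100 * frac:.3g}% non-finite {label} work values",
                      RuntimeWarning)
    if frac > MAX_EXCLUDED_FRACTION:
        raise EstimatorError(
            f"{100 * frac:.3g}% of {label} work values are non-finite "
            f"(limit {100 * MAX_EXCLUDED_FRACTION:.1g}%)")
    return phi[ok], frac


@dataclass
class WorkSet:
    """Generalized-work values on both sides of the two-state estimate.

    ``phi_model`` are phi values on model samples (the q side); ``phi_data``
    are phi values on data frames (the p side). Non-finite entries are
    excluded on construction and their fraction recorded.
    """

    phi_model: np.ndarray
    phi_data: np.ndarray
    beta: float = 1.0
    excluded_fraction_model: float = 0.0
    excluded_fraction_data: float = 0.0

    def __post_init__(self) -> None:
        self.phi_model, self.excluded_fraction_model = _clean(self.phi_model, "model-side")
        self.phi_data, self.excluded_fraction_data = _clean(self.phi_data, "data-side")

    @property
    def n_model(self) -> int:
        return self.phi_model.size

    @property
    def n_data(self) -> int:
        return self.phi_data.size


def _kish_ess(w: np.ndarray) -> float:
    """Kish effective sample size of nonnegative weights."""
    s2 = (w ** 2).sum()
    if s2 == 0:
        return 0.0
    return float(w.sum() ** 2 / s2)


def bar(w_forward: np.ndarray, w_reverse: np.ndarray) -> Tuple[float, float, dict]:
    """Two-state Bennett acceptance ratio.

    Parameters
    ----------
    w_forward : work values ``u_B - u_A`` evaluated on samples of state A
    w_reverse : work values ``u_A - u_B`` evaluated on samples of state B

    Returns ``(delta_f, se, diagnostics)`` with ``delta_f = f_B - f_A`` in
    reduced units. The standard error is the analytic (asymptotic) sandwich
    estimate from the self-consistency equation; ``diagnostics`` reports the
    per-side effective sample sizes.
    """
    wf = np.asarray(w_forward, dtype=float).ravel()
    wr = np.asarray(w_reverse, dtype=float).ravel()
    if wf.size == 0 or wr.size == 0:
        raise EstimatorError("both work populations must be non-empty")
    if not (np.all(np.isfinite(wf)) and np.all(np.isfinite(wr))):
        raise EstimatorError("work values must be finite (clean them via WorkSet)")
    n_f, n_r = wf.size, wr.size
    m = np.log(n_f / n_r)

    def h(df: float) -> float:
        # Fermi(x) = expit(-x); self-consistency: sum_F Fermi(M + wf - df)
        #                                        = sum_R Fermi(-M + wr + df)
        return expit(-(m + wf - df)).sum() - expit(-(-m + wr + df)).sum()

    # bracket the unique root of the monotone-increasing h
    center = 0.5 * (np.median(wf) - np.median(wr))
    span = 1.0 + 0.5 * (np.ptp(wf) + np.ptp(wr))
    lo, hi = center - span, center + span
    for _ in range(80):
        if h(lo) < 0 and h(hi) > 0:
            break
        lo, hi = center - 2 * (center - lo), center + 2 * (hi - center)
    else:
        raise EstimatorError("acceptance-ratio equation could not be bracketed "
                             "(no overlap between work populations)")
    df = brentq(h, lo, hi, xtol=1e-12, rtol=1e-14)

    b = expit(-(m + wf - df))      # forward Fermi factors
    a = expit(-(-m + wr + df))     # reverse Fermi factors
    slope = (b * (1 - b)).sum() + (a * (1 - a)).sum()
    var_h = n_f * b.var() + n_r * a.var()
    # overlap proxy: effective number of samples carrying acceptance weight.
    # Kish ESS catches a few dominant factors; the expected acceptance count
    # n * mean(Fermi) catches uniformly negligible acceptance (disjoint states).
    diagnostics = {
        "ess_forward": min(_kish_ess(b), n_f * float(b.mean())),
        "ess_reverse": min(_kish_ess(a), n_r * float(a.mean())),
        "mean_fermi_forward": float(b.mean()),
        "mean_fermi_reverse": float(a.mean()),
    }
    if slope <= 0:
        return float(df), float("inf"), diagnostics
    se = float(np.sqrt(var_h) / slope)
    return float(df), se, diagnostics


def bar_v(workset: WorkSet, index: Optional[int] = None) -> FreeEnergyEstimate:
    """Absolute ``f = -ln Z`` of the physical state via BAR against the model.

    State A is the normalized model (reduced potential ``-ln q``, free energy
    0); state B is the physical state (reduced potential ``beta U``). The
    forward work on model samples and the reverse work on data frames are
    then ``+phi`` and ``-phi`` respectively.

    If either side's effective sample size falls below ``MIN_ESS`` the
    estimate is flagged and returned with an infinite standard error.
    """
    df, se, diag = bar(workset.phi_model, -workset.phi_data)
    diag["excluded_fraction_model"] = workset.excluded_fraction_model
    diag["excluded_fraction_data"] = workset.excluded_fraction_data
    flagged = min(diag["ess_forward"], diag["ess_reverse"]) <= MIN_ESS
    diag["overlap_ok"] = not flagged
    if flagged:
        warnings.warn("insufficient overlap between model and data work "
                      "populations; standard error is unreliable", RuntimeWarning)
        se = float("inf")
    return FreeEnergyEstimate(f=df, se=se, tag="BAR_V", index=index, diagnostics=diag)


def free_energy_ml(phi_data: np.ndarray, index: Optional[int] = None) -> FreeEnergyEstimate:
    """ML-side estimate ``f_ML = <phi>`` over validation frames.

    By Gibbs' inequality ``E_p[phi] = f - KL(p || q) <= f``: a lower bound in
    expectation, tight when the model matches the Boltzmann density."""
    phi, frac = _clean(phi_data, "data-side")
    se = float(phi.std(ddof=1) / np.sqrt(phi.size)) if phi.size > 1 else float("inf")
    return FreeEnergyEstimate(f=float(phi.mean()), se=se, tag="ML", index=index,
                              diagnostics={"excluded_fraction": frac})


def softmax_weights(f_ml: Sequence[float]) -> np.ndarray:
    """Weights proportional to ``exp(f_ML_j - max_k f_ML_k)``.

    ``f_ML`` is a lower bound on f that rises as the model improves and
    decays again when it overfits, so these weights concentrate on the
    best-trained evaluations.
    """
    f = np.asarray(f_ml, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one estimate")
    w = np.exp(f - f.max())
    return w / w.sum()


def weighted_running_average(f: Sequence[float], se: Sequence[float],
                             weights: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative weighted averages ``fbar(i)`` with SEs averaged identically.

    Returns arrays of length ``len(f)``; entry ``i`` uses estimates
    ``1..i+1``. Weight rescaling leaves the result invariant; an all-zero
    weight vector falls back to uniform weights with a warning.
    """
    f = np.asarray(f, dtype=float)
    se = np.asarray(se, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (f.shape == se.shape == w.shape) or f.ndim != 1 or f.size == 0:
        raise ValueError("f, se and weights must be equal-length non-empty 1-D arrays")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        warnings.warn("all-zero weights; falling back to uniform", RuntimeWarning)
        w = np.ones_like(w)
    cw = np.cumsum(w)
    fbar = np.cumsum(w * f) / cw
    sebar = np.cumsum(w * se) / cw
    return fbar, sebar


def entropy_per_molecule(mean_beta_u: float, f: float, n_mol: int) -> float:
    """Per-molecule reduced entropy ``s = (<beta U> - f) / n_mol`` (units k_B)."""
    if n_mol <= 0:
        raise ValueError("n_mol must be positive")
    return (mean_beta_u - f) / n_mol
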
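"""Maximum-likelihood training of flow models with periodic BAR evaluation.

The loss is the negative mean generalized work, ``-<beta U + ln q>``, over a
training batch: since ``beta U`` does not depend on model parameters its
gradient vanishes and minimizing the loss is exactly maximum likelihood on
``ln q``. By Gibbs' inequality ``<phi>`` over data is a lower bound on the
reduced free energy f, tight when the model matches the Boltzmann density, so
the loss decreasing toward ``-f`` is a direct convergence diagnostic.

Every ``eval_stride`` training batches the loop draws a random validation
batch and an equally sized set of model samples, records the two-state
acceptance-ratio estimate ``f_BAR_V`` with its analytic standard error and the
ML-side estimate ``f_ML = <phi>``, and updates the softmax-weighted running
average. Training stops at a hard step cap or when the running average
plateaus.
"""

from __future__ import annotations

import csv
import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from ._ad import Tensor
from . import estimators
from .estimators import EstimatorError, FreeEnergyEstimate, WorkSet
from .flow import FlowModel
from .frames import Ensemble

__all__ = ["TrainingConfig", "EvalRecord", "TrainingResult", "Adam",
           "split_dataset", "ml_loss", "train"]


@dataclass
class TrainingConfig:
    """Batch sizes, split and cadence of the training loop.

    The defaults (1000-frame training batches, 10^4-frame evaluation batches,
    3:1 train:validation split, 25 batches between evaluations, Adam at
    learning rate 1e-3) are the production settings; scale them down for desk
    experiments.
    """

    train_batch: int = 1000
    eval_batch: int = 10_000
    train_fraction: float = 0.75      # 3:1 split
    eval_stride: int = 25
    learning_rate: float = 1e-3
    max_steps: int = 2000
    seed: int = 0
    plateau_rel_tol: float = 1e-3
    plateau_window_frac: float = 0.25
    min_evals_for_plateau: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("train_batch", "eval_batch", "eval_stride", "max_steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class EvalRecord:
    """One periodic evaluation along a training run."""

    index: int                 # evaluation counter (1-based)
    step: int                  # training batches completed
    f_bar_v: float
    se_bar_v: float
    f_ml: float
    se_ml: float
    running_f: float
    running_se: float
    overlap_ok: bool
    loss: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrainingResult:
    records: List[EvalRecord]
    final_estimate: FreeEnergyEstimate
    skipped_batches: int
    steps_run: int
    stopped_on_plateau: bool
    best_parameters: Optional[List[np.ndarray]] = None


class Adam:
    """Adam optimizer over a flat list of numpy parameter arrays."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def split_dataset(n_frames: int, train_fraction: float,
                  rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Random frame-level split applied once, before any fitting."""
    perm = rng.permutation(n_frames)
    n_train = int(round(train_fraction * n_frames))
    if n_train < 1 or n_train >= n_frames:
        raise ValueError("split leaves an empty train or validation set")
    return perm[:n_train], perm[n_train:]


def ml_loss(model: FlowModel, coords: np.ndarray, beta_u: np.ndarray):
    """Differentiable loss ``-<beta U + ln q>`` over one batch.

    Returns ``(loss Tensor, parameter Tensors)``; call ``loss.backward()``
    and read the gradients off the returned parameters. The ``beta_u`` term
    is an additive constant for the gradient but keeps the loss value on the
    ``-f`` scale.
    """
    x, fixed = model.preprocess(coords)
    params = [Tensor(p) for p in model.coupling_parameters()]
    z, ld = model.couplings_forward_ad(Tensor(x), params)
    ln_q = model.base_logpdf_ad(z) + ld + Tensor(fixed)
    loss = -(ln_q + Tensor(np.asarray(beta_u, dtype=float))).mean()
    return loss, params


def _evaluate(model: FlowModel, data: Ensemble, beta_u: np.ndarray,
              valid_idx: np.ndarray, potential: Callable[[np.ndarray], np.ndarray],
              cfg: TrainingConfig, rng: np.random.Generator, index: int, step: int,
              replaced_warned: List[bool]):
    n_valid = valid_idx.size
    replace = cfg.eval_batch > n_valid
    if replace and not replaced_warned[0]:
        warnings.warn("evaluation batch exceeds validation set; sampling with replacement",
                      RuntimeWarning)
        replaced_warned[0] = True
    pick = rng.choice(valid_idx, size=min(cfg.eval_batch, n_valid) if not replace else cfg.eval_batch,
                      replace=replace)
    coords_v = data.coords[pick]
    phi_data = beta_u[pick] + model.log_prob(coords_v)

    coords_m, ln_q_m = model.sample(cfg.eval_batch, rng)
    phi_model = potential(coords_m) + ln_q_m

    ml = estimators.free_energy_ml(phi_data, index=index)
    try:
        est = estimators.bar_v(WorkSet(phi_model, phi_data), index=index)
    except EstimatorError as exc:
        warnings.warn(f"evaluation {index}: acceptance-ratio estimate failed ({exc})",
                      RuntimeWarning)
        est = FreeEnergyEstimate(f=float("nan"), se=float("inf"), tag="BAR_V", index=index,
                                 diagnostics={"overlap_ok": False})
    return est, ml


def train(model: FlowModel, data: Ensemble, beta_u: np.ndarray,
          potential: Callable[[np.ndarray], np.ndarray],
          config: Optional[TrainingConfig] = None,
          out_dir: Optional[str] = None,
          keep_best_parameters: bool = False) -> TrainingResult:
    """Run the training loop; fully deterministic given (seed, config, data).

    Parameters
    ----------
    model : an initialized :class:`FlowModel` (fixed layers already fitted)
    data : MD (or synthetic) ensemble
    beta_u : (n_frames,) reduced potentials aligned with ``data``
    potential : maps generated coordinates (F, n_atoms, 3) to reduced
        potentials (F,) — the physical energy oracle for model samples
    out_dir : if given, evaluation records are streamed to ``metrics.csv``
        and ``log.jsonl`` inside it
    """
    cfg = TrainingConfig() if config is None else config
    beta_u = np.asarray(beta_u, dtype=float)
    if beta_u.shape != (len(data),):
        raise ValueError("beta_u must align with the data frames")
    rng = np.random.default_rng(cfg.seed)
    train_idx, valid_idx = split_dataset(len(data), cfg.train_fraction, rng)

    params = model.coupling_parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    records: List[EvalRecord] = []
    f_mls: List[float] = []
    running_f = running_se = float("nan")
    skipped = 0
    stopped_on_plateau = False
    replaced_warned = [False]
    best: Optional[List[np.ndarray]] = None
    best_f_ml = -np.inf
    last_loss = float("nan")

    csv_file = jsonl_file = None
    csv_writer = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        csv_file = open(os.path.join(out_dir, "metrics.csv"), "w", newline="")
        csv_writer = csv.writer(csv_file)
        csv_writer.writerow(["index", "step", "f_bar_v", "se_bar_v", "f_ml", "se_ml",
                             "running_f", "running_se", "overlap_ok", "loss"])
        jsonl_file = open(os.path.join(out_dir, "log.jsonl"), "w")

    try:
        step = 0
        while step < cfg.max_steps:
            step += 1
            batch = rng.choice(train_idx, size=min(cfg.train_batch, train_idx.size),
                               replace=cfg.train_batch > train_idx.size)
            loss, p_tensors = ml_loss(model, data.coords[batch], beta_u[batch])
            if not np.isfinite(loss.data):
                skipped += 1
                warnings.warn(f"step {step}: non-finite loss; batch skipped", RuntimeWarning)
                continue
            loss.backward()
            grads = [pt.grad if pt.grad is not None else np.zeros_like(pt.data)
                     for pt in p_tensors]
            if not all(np.all(np.isfinite(g)) for g in grads):
                skipped += 1
                warnings.warn(f"step {step}: non-finite gradient; batch skipped", RuntimeWarning)
                continue
            opt.step(grads)
            model.set_coupling_parameters(params)
            last_loss = float(loss.data)

            if step % cfg.eval_stride == 0:
                index = len(records) + 1
                est, ml = _evaluate(model, data, beta_u, valid_idx, potential,
                                    cfg, rng, index, step, replaced_warned)
                f_mls.append(ml.f)
                # flagged (no-overlap) evaluations carry an infinite SE and are
                # excluded from the running average
                usable = np.isfinite(est.f) and np.isfinite(est.se)
                finite = [i for i, r in enumerate(records)
                          if np.isfinite(r.f_bar_v) and np.isfinite(r.se_bar_v)]
                fs = [records[i].f_bar_v for i in finite] + ([est.f] if usable else [])
                ses = [records[i].se_bar_v for i in finite] + ([est.se] if usable else [])
                wml = [f_mls[i] for i in finite] + ([ml.f] if usable else [])
                if fs:
                    w = estimators.softmax_weights(wml)
                    fbar, sebar = estimators.weighted_running_average(fs, ses, w)
                    running_f, running_se = float(fbar[-1]), float(sebar[-1])
                rec = EvalRecord(index=index, step=step, f_bar_v=est.f, se_bar_v=est.se,
                                 f_ml=ml.f, se_ml=ml.se, running_f=running_f,
                                 running_se=running_se,
                                 overlap_ok=bool(est.diagnostics.get("overlap_ok", False)),
                                 loss=last_loss)
                records.append(rec)
                if csv_writer is not None:
                    csv_writer.writerow([rec.index, rec.step, rec.f_bar_v, rec.se_bar_v,
                                         rec.f_ml, rec.se_ml, rec.running_f, rec.running_se,
                                         rec.overlap_ok, rec.loss])
                    csv_file.flush()
                    jsonl_file.write(json.dumps(rec.as_dict()) + "\n")
                    jsonl_file.flush()
                if keep_best_parameters and ml.f > best_f_ml:
                    best_f_ml = ml.f
                    best = [p.copy() for p in params]
                if _plateaued(records, cfg):
                    stopped_on_plateau = True
                    break
    finally:
        if csv_file is not None:
            csv_file.close()
            jsonl_file.close()

    final = FreeEnergyEstimate(
        f=running_f if np.isfinite(running_f) else float("nan"),
        se=running_se if np.isfinite(running_se) else float("inf"),
        tag="BAR_V", index=len(records),
        diagnostics={"weighted_running_average": True, "skipped_batches": skipped})
    return TrainingResult(records=records, final_estimate=final, skipped_batches=skipped,
                          steps_run=step, stopped_on_plateau=stopped_on_plateau,
                          best_parameters=best)


def _plateaued(records: List[EvalRecord], cfg: TrainingConfig) -> bool:
    """Relative change of the running average below tolerance over the last
    quarter (by default) of the evaluations."""
    n = len(records)
    if n < cfg.min_evals_for_plateau:
        return False
    window = max(2, int(np.ceil(cfg.plateau_window_frac * n)))
    tail = np.array([r.running_f for r in records[-window:]])
    if not np.all(np.isfinite(tail)):
        return False
    scale = max(1.0, abs(tail[-1]))
    return bool(np.max(np.abs(tail - tail[-1])) / scale < cfg.plateau_rel_tol)
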
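"""Loss, batching, optimization schedule, and evaluation metrics.

The loss is  L = alpha * MSE(V) + beta * MSE(gradient components, QM and
MM atoms alike) + gamma * MSE(molecular dipole and quadrupole
components), with alpha = 0.99, beta = 100, gamma = 100 by default.
Optimization uses Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-7), an
exponential learning-rate decay to 2% of the initial rate over the run,
and global-norm gradient clipping at 1.  The checkpoint kept is the one
with the lowest validation loss; runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from . import autodiff as ad
from .coupling import model_energy_var
from .model import AMPModel
from .system import SimulationSystem


@dataclass
class TrainingExample:
    """One labeled snapshot: system plus reference energy (kJ/mol),
    gradients (kJ/mol/A) and molecular multipoles (e*A, e*A^2)."""

    system: SimulationSystem
    V_ref: float
    grad_qm_ref: np.ndarray
    grad_mm_ref: np.ndarray
    dipole_ref: np.ndarray
    quadrupole_ref: np.ndarray


@dataclass
class TrainingConfig:
    lr_initial: float = 5e-4
    decay_gamma: float = 0.02      # lr decays to this fraction over the run
    batch_size: int = 16
    clip_norm: float = 1.0
    alpha: float = 0.99            # energy weight
    beta: float = 100.0            # gradient weight
    gamma_mp: float = 100.0        # multipole weight
    epochs: int = 100
    seed: int = 0
    relative_energy_mode: str = "median_shift"
    precision: str = "float32"     # training dtype; inference uses float64
    validate_every: int = 1        # epochs between validation evaluations

    def __post_init__(self):
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be float32 or float64")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("lr_initial", "decay_gamma", "batch_size", "clip_norm",
                     "beta", "gamma_mp", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.relative_energy_mode not in ("median_shift",
                                             "per_batch_relative"):
            raise ValueError("unknown relative_energy_mode")


# -- target preparation -------------------------------------------------

def relative_to_batch_mean(values) -> np.ndarray:
    """Energies of one single-system batch relative to the batch mean."""
    v = np.asarray(values)
    if v.dtype not in (np.float32, np.float64):
        v = v.astype(float)
    return v - v.mean()


def prepare_targets(dataset: List[TrainingExample],
                    cfg: TrainingConfig,
                    shift: Optional[float] = None):
    """Apply the energy-offset convention of ``cfg``.

    ``median_shift`` subtracts the dataset median (or an explicit
    ``shift``, so validation/test sets can reuse the training shift);
    ``per_batch_relative`` leaves labels untouched (the offset is applied
    per batch during training) but verifies the dataset holds a single
    molecular system.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if cfg.relative_energy_mode == "median_shift":
        if shift is None:
            shift = float(np.median([ex.V_ref for ex in dataset]))
        return [replace(ex, V_ref=ex.V_ref - shift) for ex in dataset], shift
    z0 = tuple(dataset[0].system.qm.atomic_numbers)
    for ex in dataset:
        if tuple(ex.system.qm.atomic_numbers) != z0:
            raise ValueError(
                "per_batch_relative requires batches of one molecular system")
    return list(dataset), 0.0


# -- batching -----------------------------------------------------------

class Batch:
    """Stacked arrays for examples sharing one QM topology; MM arrays are
    zero-padded (zero charge, zero LJ epsilon, far-away position)."""

    def __init__(self, examples: List[TrainingExample], dtype=np.float64):
        self.dtype = dtype
        z0 = tuple(examples[0].system.qm.atomic_numbers)
        for ex in examples:
            if tuple(ex.system.qm.atomic_numbers) != z0:
                raise ValueError("batch mixes molecular systems")
        self.Z = np.array(z0)
        n = len(self.Z)
        b = len(examples)
        m_max = max(ex.system.mm.n_atoms for ex in examples)
        self.R = np.stack([ex.system.qm.positions for ex in examples])
        self.Rm = np.zeros((b, m_max, 3))
        self.Qm = np.zeros((b, m_max))
        self.grad_mm = np.zeros((b, m_max, 3))
        lj_eps = np.zeros(m_max)
        lj_sig = np.ones(m_max)
        for k, ex in enumerate(examples):
            mm = ex.system.mm
            nm = mm.n_atoms
            self.Rm[k, :nm] = mm.positions
            # padding sites sit far outside every cutoff (kept moderate so
            # high powers of r in nested derivatives stay in float32 range)
            self.Rm[k, nm:] = ex.system.qm.positions.mean(axis=0) + 50.0
            self.Qm[k, :nm] = mm.charges
            if ex.grad_mm_ref is not None:
                self.grad_mm[k, :nm] = ex.grad_mm_ref
            lj_eps[:nm] = mm.lj_epsilon
            lj_sig[:nm] = mm.lj_sigma
        self.mm_lj = (lj_eps, lj_sig)
        qm = examples[0].system.qm
        self.qm_lj = (
            qm.lj_epsilon if qm.lj_epsilon is not None else np.zeros(n),
            qm.lj_sigma if qm.lj_sigma is not None else np.ones(n))
        self.total_charge = qm.total_charge
        self.V_ref = np.array([ex.V_ref for ex in examples])
        self.grad_qm = np.stack([ex.grad_qm_ref for ex in examples])
        self.dipole = np.stack([ex.dipole_ref for ex in examples])
        self.quadrupole = np.stack([ex.quadrupole_ref for ex in examples])
        for name in ("R", "Rm", "Qm", "grad_mm", "V_ref", "grad_qm",
                     "dipole", "quadrupole"):
            setattr(self, name, getattr(self, name).astype(dtype))
        self.mm_lj = tuple(a.astype(dtype) for a in self.mm_lj)
        self.qm_lj = tuple(np.asarray(a, dtype=dtype) for a in self.qm_lj)
        # full directed QM pair list; the smooth envelope reproduces the
        # cutoff graph exactly, so one shared edge list serves the batch
        src, dst = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        off = ~np.eye(n, dtype=bool)
        self.edges = (src[off], dst[off])
        eq, em = np.meshgrid(np.arange(n), np.arange(m_max), indexing="ij")
        self.mm_pairs = (eq.ravel(), em.ravel())
        self.has_mm = m_max > 0


def batch_predict(model: AMPModel, p: dict, batch: Batch,
                  need_gradients: bool = True):
    """Differentiable predictions for one batch.

    Returns dict of Vars: V (B,), grad_qm, grad_mm, dipole, quadrupole.
    """
    R = ad.Var(batch.R)
    mm = None
    Rm = None
    if batch.has_mm:
        Rm = ad.Var(batch.Rm)
        mm = {"R": Rm, "q": ad.Var(batch.Qm), "pol_pairs": batch.mm_pairs,
              "es_pairs": batch.mm_pairs, "lj_eps": batch.mm_lj[0],
              "lj_sig": batch.mm_lj[1]}
    out, terms = model_energy_var(model, p, batch.Z, R, batch.edges,
                                  total_charge=batch.total_charge, mm=mm,
                                  qm_lj=batch.qm_lj)
    V = ad.add(ad.add(terms["V_AMP"], terms["V_ES_QM"]),
               ad.add(terms["V_ES_QMMM"], terms["V_LJ_QMMM"]))
    pred = {"V": V}

    B, n = batch.R.shape[:2]
    centroid = ad.mul(ad.vsum(R, axis=1, keepdims=True), 1.0 / n)
    d = ad.sub(R, centroid)
    q3 = ad.reshape(out.q, (B, n, 1))
    pred["dipole"] = ad.add(ad.vsum(ad.mul(q3, d), axis=1),
                            ad.vsum(out.es_mu, axis=1))
    dd = ad.mul(ad.reshape(d, (B, n, 3, 1)), ad.reshape(d, (B, n, 1, 3)))
    mu_d = ad.add(
        ad.mul(ad.reshape(out.es_mu, (B, n, 3, 1)),
               ad.reshape(d, (B, n, 1, 3))),
        ad.mul(ad.reshape(d, (B, n, 3, 1)),
               ad.reshape(out.es_mu, (B, n, 1, 3))))
    pred["quadrupole"] = ad.add(
        ad.vsum(ad.add(ad.mul(ad.reshape(q3, (B, n, 1, 1)), dd), mu_d), axis=1),
        ad.vsum(out.es_theta, axis=1))

    if need_gradients:
        wrt = [R] + ([Rm] if Rm is not None else [])
        grads = ad.grad(ad.vsum(V), wrt)
        pred["grad_qm"] = grads[0]
        if Rm is not None:
            pred["grad_mm"] = grads[1]
    return pred


# -- loss ---------------------------------------------------------------

def loss(pred: dict, ref: dict, cfg: TrainingConfig) -> float:
    """Numpy loss on arrays (keys V, grad, dipole, quadrupole); the
    training loop uses the identical Var formulation."""
    for key in pred:
        if np.shape(pred[key]) != np.shape(ref[key]):
            raise ValueError(f"shape mismatch for {key}")
    total = cfg.alpha * np.mean((np.asarray(pred["V"]) - ref["V"]) ** 2)
    if "grad" in pred:
        total += cfg.beta * np.mean((pred["grad"] - ref["grad"]) ** 2)
    if "dipole" in pred:
        dmp = np.concatenate([
            (pred["dipole"] - ref["dipole"]).reshape(len(ref["dipole"]), -1),
            (pred["quadrupole"] - ref["quadrupole"]).reshape(
                len(ref["quadrupole"]), -1)], axis=1)
        total += cfg.gamma_mp * np.mean(dmp ** 2)
    return float(total)


def _loss_var(pred: dict, batch: Batch, cfg: TrainingConfig) -> ad.Var:
    v_ref = batch.V_ref
    v_pred = pred["V"]
    if cfg.relative_energy_mode == "per_batch_relative":
        v_ref = relative_to_batch_mean(v_ref)
        v_pred = ad.sub(v_pred, ad.vmean(v_pred))
    total = ad.mul(ad.vmean(ad.power(ad.sub(v_pred, v_ref), 2.0)), cfg.alpha)

    n_comp = batch.grad_qm.size + batch.grad_mm.size
    sq = ad.vsum(ad.power(ad.sub(pred["grad_qm"], batch.grad_qm), 2.0))
    if "grad_mm" in pred:
        sq = ad.add(sq, ad.vsum(ad.power(
            ad.sub(pred["grad_mm"], batch.grad_mm), 2.0)))
    total = ad.add(total, ad.mul(sq, cfg.beta / n_comp))

    n_mp = batch.dipole.size + batch.quadrupole.size
    sq_mp = ad.add(
        ad.vsum(ad.power(ad.sub(pred["dipole"], batch.dipole), 2.0)),
        ad.vsum(ad.power(ad.sub(pred["quadrupole"], batch.quadrupole), 2.0)))
    return ad.add(total, ad.mul(sq_mp, cfg.gamma_mp / n_mp))


# -- optimizer ----------------------------------------------------------

class Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_by_global_norm(grads: dict, clip: float) -> dict:
    norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if norm > clip:
        scale = clip / norm
        return {k: g * scale for k, g in grads.items()}, norm
    return grads, norm


def train(model: AMPModel, train_set: List[TrainingExample],
          cfg: TrainingConfig, val_set: Optional[List[TrainingExample]] = None):
    """Optimize the model in place; returns the per-epoch history.

    The parameters kept at the end are those of the epoch with the lowest
    validation loss (training loss when no validation set is given).
    """
    train_set, shift = prepare_targets(train_set, cfg)
    if val_set:
        val_set, _ = prepare_targets(val_set, cfg, shift=shift)
    rng = np.random.default_rng(cfg.seed)
    names = list(model.params)
    opt = Adam(model.params, cfg.lr_initial)
    history = []
    best = (np.inf, copy.deepcopy(model.params))

    n = len(train_set)
    for epoch in range(cfg.epochs):
        frac = epoch / max(cfg.epochs - 1, 1)
        opt.lr = cfg.lr_initial * cfg.decay_gamma ** frac
        order = rng.permutation(n)
        ep_loss = 0.0
        dtype = np.float32 if cfg.precision == "float32" else np.float64
        for lo in range(0, n, cfg.batch_size):
            batch = Batch([train_set[i] for i in order[lo:lo + cfg.batch_size]],
                          dtype=dtype)
            p = model.param_vars(dtype)
            L = _loss_var(batch_predict(model, p, batch), batch, cfg)
            if not np.isfinite(L.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch offset {lo}")
            gs = ad.grad(L, [p[k] for k in names])
            grads = {k: g.data.astype(np.float64) for k, g in zip(names, gs)}
            grads, _ = clip_by_global_norm(grads, cfg.clip_norm)
            opt.step(model.params, grads)
            ep_loss += float(L.data) * len(batch.V_ref)
        ep_loss /= n

        last = epoch == cfg.epochs - 1
        if val_set and (epoch % cfg.validate_every == 0 or last):
            val_loss = _dataset_loss(model, val_set, cfg)
        else:
            val_loss = ep_loss if not val_set else None
        history.append({"epoch": epoch, "train_loss": ep_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss is not None and val_loss < best[0]:
            best = (val_loss, copy.deepcopy(model.params))

    model.params.update(best[1])
    return history


def _dataset_loss(model, dataset, cfg, chunk: int = 256) -> float:
    total, count = 0.0, 0
    dtype = np.float32 if cfg.precision == "float32" else np.float64
    for lo in range(0, len(dataset), chunk):
        batch = Batch(dataset[lo:lo + chunk], dtype=dtype)
        p = model.param_vars(dtype)
        L = _loss_var(batch_predict(model, p, batch), batch, cfg)
        total += float(L.data) * len(batch.V_ref)
        count += len(batch.V_ref)
    return total / count


def evaluate_metrics(model: AMPModel, dataset: List[TrainingExample],
                     energy_shift: float = None, chunk: int = 256) -> dict:
    """MAE and maximum unsigned error for energies, gradient components,
    dipoles and quadrupoles.

    When ``energy_shift`` is None the reported energy errors are computed
    after removing the mean offset (predictions live on the shifted scale
    used in training; only relative energies are physical).
    """
    dv, dg, dd, dq = [], [], [], []
    for lo in range(0, len(dataset), chunk):
        batch = Batch(dataset[lo:lo + chunk])
        p = model.param_vars()
        pred = batch_predict(model, p, batch)
        dv.append(pred["V"].data - batch.V_ref)
        dg.append((pred["grad_qm"].data - batch.grad_qm).ravel())
        if "grad_mm" in pred:
            dg.append((pred["grad_mm"].data - batch.grad_mm).ravel())
        dd.append((pred["dipole"].data - batch.dipole).ravel())
        dq.append((pred["quadrupole"].data - batch.quadrupole).ravel())
    dv = np.concatenate(dv)
    dv -= np.mean(dv) if energy_shift is None else energy_shift
    dg, dd, dq = (np.concatenate(a) for a in (dg, dd, dq))
    out = {}
    for name, err in (("energy", dv), ("gradient", dg),
                      ("dipole", dd), ("quadrupole", dq)):
        out[f"mae_{name}"] = float(np.mean(np.abs(err)))
        out[f"maxue_{name}"] = float(np.max(np.abs(err)))
    return out


def example_to_frame(ex: TrainingExample):
    from .system import Frame, Labels

    return Frame(ex.system, Labels(
        energy=ex.V_ref, grad_qm=ex.grad_qm_ref, grad_mm=ex.grad_mm_ref,
        dipole=ex.dipole_ref, quadrupole=ex.quadrupole_ref))


def frame_to_example(frame) -> TrainingExample:
    sys_, labels = frame
    if labels is None or labels.energy is None:
        raise ValueError("frame carries no energy label")
    n_mm = sys_.mm.n_atoms
    return TrainingExample(
        system=sys_, V_ref=labels.energy, grad_qm_ref=labels.grad_qm,
        grad_mm_ref=(labels.grad_mm if labels.grad_mm is not None
                     else np.zeros((n_mm, 3))),
        dipole_ref=labels.dipole, quadrupole_ref=labels.quadrupole)


def save_dataset(directory, splits: dict):
    """Write train/val/test splits as extended-XYZ files."""
    from pathlib import Path

    from .system import write_extxyz

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, examples in splits.items():
        write_extxyz(directory / f"{name}.xyz",
                     [example_to_frame(ex) for ex in examples])


def load_dataset(directory) -> dict:
    from pathlib import Path

    from .system import read_extxyz

    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.xyz")):
        out[path.stem] = [frame_to_example(f) for f in read_extxyz(path)]
    return out


def train_repeated(make_model, train_set, cfg: TrainingConfig, val_set,
                   epoch_schedule=(1, 2, 3)):
    """Optional driver: several runs with increasing epoch counts and the
    same decay factor; keeps the run with the lowest validation gradient
    MSE.  ``make_model(seed)`` must return a fresh model."""
    best = None
    for k, epochs in enumerate(epoch_schedule):
        model = make_model(cfg.seed + k)
        run_cfg = replace(cfg, epochs=epochs, seed=cfg.seed + k)
        history = train(model, train_set, run_cfg, val_set)
        metrics = evaluate_metrics(model, val_set)
        score = metrics["mae_gradient"]
        if best is None or score < best[0]:
            best = (score, model, history)
    return best[1], best[2]
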
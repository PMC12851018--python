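"""Fitting the potential to labeled frames.

The loss is a weighted sum of per-atom-normalised energy MSE, force MSE and
per-channel spin-charge MSE.  Force residuals are differentiated through
the reverse-mode gradient itself (double backpropagation), so force
supervision shapes the parameters directly.  Optimisation is Adam with a
plateau-halving learning-rate schedule, early stopping on validation loss
and a best-checkpoint return.  All randomness flows from the single seed in
:class:`LossConfig`; fixed seed implies bit-identical training runs.

Per-element reference energy shifts are fitted by ordinary linear
regression on the training compositions before network training; they carry
the arbitrary energy zero so the network only learns residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Tensor, grad, tensor
from .model import ModelConfig, NSEPotential, _Batch
from .surrogate import LabeledFrame

logger = logging.getLogger(__name__)

__all__ = ["LossConfig", "loss", "train", "train_ensemble", "fit_reference_shifts"]


@dataclass
class LossConfig:
    w_energy: float = 1.0
    w_force: float = 0.5
    w_charge: float = 1.0
    batch_size: int = 64
    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 30            # early-stop patience (epochs)
    plateau_patience: int = 10    # epochs without improvement before lr halving
    lr_decay: float = 0.5
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if min(self.w_energy, self.w_force, self.w_charge) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.w_energy == self.w_force == self.w_charge == 0:
            raise ValueError("at least one loss weight must be positive")


class _PreparedBatch:
    """A `_Batch` plus reference label arrays, built once and reused."""

    def __init__(self, frames: Sequence[LabeledFrame], cutoff: float):
        self.batch = _Batch([f.system for f in frames], cutoff)
        self.e_ref = np.array([f.energy for f in frames])
        self.f_ref = np.concatenate([f.forces for f in frames], axis=0)
        self.qa_ref = np.concatenate([f.q_alpha for f in frames])
        self.qb_ref = np.concatenate([f.q_beta for f in frames])


def _loss_graph(model: NSEPotential, prepared: _PreparedBatch, config: LossConfig):
    """Total loss Tensor plus float components for one batch."""
    batch = prepared.batch
    need_forces = config.w_force > 0
    coords = Tensor(batch.coords, requires_grad=need_forces)
    energy, qa, qb, *_ = model._forward_graph(batch, coords)
    total = tensor(0.0)
    components = {}
    if config.w_energy > 0:
        res = (energy - prepared.e_ref) / batch.n_atoms_per_frame
        l_e = (res * res).mean()
        total = total + config.w_energy * l_e
        components["energy"] = l_e.item()
    if need_forces:
        f_pred = -grad(energy.sum(), coords)
        df = f_pred - prepared.f_ref
        l_f = (df * df).mean()
        total = total + config.w_force * l_f
        components["force"] = l_f.item()
    if config.w_charge > 0:
        da = qa - prepared.qa_ref
        db = qb - prepared.qb_ref
        l_q = (da * da).mean() + (db * db).mean()
        total = total + config.w_charge * l_q
        components["charge"] = l_q.item()
    return total, components


def loss(model: NSEPotential, frames: Sequence[LabeledFrame],
         config: Optional[LossConfig] = None) -> Tuple[float, dict]:
    """Scalar training loss and its components on a batch of frames.

    Zero iff the model reproduces every supervised label exactly (for
    positive weights); invariant to the ordering of frames in the batch.
    """
    if len(frames) == 0:
        raise ValueError("empty batch")
    config = config or LossConfig()
    prepared = _PreparedBatch(frames, model.config.cutoff)
    total, components = _loss_graph(model, prepared, config)
    return total.item(), components


def fit_reference_shifts(frames: Sequence[LabeledFrame], elements: Sequence[int]) -> np.ndarray:
    """Least-squares per-element energy offsets from composition counts."""
    counts = np.zeros((len(frames), len(elements)))
    for k, f in enumerate(frames):
        for i, z in enumerate(elements):
            counts[k, i] = np.count_nonzero(f.system.atomic_numbers == z)
    energies = np.array([f.energy for f in frames])
    shifts, *_ = np.linalg.lstsq(counts, energies, rcond=None)
    return shifts


def _conservation_spot_check(model, prepared: _PreparedBatch, atol: float = 1e-8):
    coords = Tensor(prepared.batch.coords)
    _, qa, qb, *_ = model._forward_graph(prepared.batch, coords)
    b = prepared.batch
    sums_a = np.bincount(b.frame_ids, weights=qa.value, minlength=b.n_frames)
    sums_b = np.bincount(b.frame_ids, weights=qb.value, minlength=b.n_frames)
    err = max(np.abs(sums_a - b.totals_alpha).max(), np.abs(sums_b - b.totals_beta).max())
    if err > atol:
        raise AssertionError(f"spin-charge conservation violated during training: {err:.2e}")


def train(model: NSEPotential, train_frames: Sequence[LabeledFrame],
          val_frames: Sequence[LabeledFrame], config: Optional[LossConfig] = None):
    """Fit `model` (on a copy) and return (best_model, history).

    History is a list of per-epoch dicts with component losses.  Divergence
    (non-finite loss) aborts with a diagnostic.
    """
    config = config or LossConfig()
    rng = np.random.default_rng(config.seed)
    model = model.copy()
    model.element_shifts = fit_reference_shifts(train_frames, model.config.elements)

    order = rng.permutation(len(train_frames))
    batches = [
        _PreparedBatch([train_frames[i] for i in order[k:k + config.batch_size]],
                       model.config.cutoff)
        for k in range(0, len(order), config.batch_size)
    ]
    val_prepared = _PreparedBatch(val_frames, model.config.cutoff) if len(val_frames) else None

    param_keys = sorted(model.params)
    m_state = {k: np.zeros_like(model.params[k].value) for k in param_keys}
    v_state = {k: np.zeros_like(model.params[k].value) for k in param_keys}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.lr
    step = 0
    best_val = np.inf
    best_params = None
    best_shifts = model.element_shifts.copy()
    since_improve = 0
    since_decay = 0
    history: List[dict] = []

    for epoch in range(config.max_epochs):
        epoch_components: dict = {}
        n_batches = 0
        for bi in rng.permutation(len(batches)):
            prepared = batches[bi]
            total, components = _loss_graph(model, prepared, config)
            if not np.isfinite(total.value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={total.value!r}, "
                    f"components={components}"
                )
            params = [model.params[k] for k in param_keys]
            grads = grad(total, params)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for k, p, g in zip(param_keys, params, grads):
                gv = g.value
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gv
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gv * gv
                p.value = p.value - lr * (m_state[k] / bc1) / (np.sqrt(v_state[k] / bc2) + eps)
            for key, val in components.items():
                epoch_components[key] = epoch_components.get(key, 0.0) + val
            n_batches += 1
        record = {"epoch": epoch, "lr": lr}
        for key, val in epoch_components.items():
            record[f"train_{key}"] = val / n_batches
        _conservation_spot_check(model, batches[0])
        if val_prepared is not None:
            val_total, val_components = _loss_graph(model, val_prepared, config)
            record["val_total"] = val_total.item()
            for key, val in val_components.items():
                record[f"val_{key}"] = val
            monitored = val_total.item()
        else:
            monitored = sum(v for k, v in record.items() if k.startswith("train_"))
            record["val_total"] = monitored
        history.append(record)
        if monitored < best_val - 1e-12:
            best_val = monitored
            best_params = {k: model.params[k].value.copy() for k in param_keys}
            best_shifts = model.element_shifts.copy()
            since_improve = 0
            since_decay = 0
        else:
            since_improve += 1
            since_decay += 1
            if since_decay >= config.plateau_patience and lr > config.min_lr:
                lr = max(lr * config.lr_decay, config.min_lr)
                since_decay = 0
                logger.info("epoch %d: lr reduced to %g", epoch, lr)
            if since_improve >= config.patience:
                logger.info("early stop at epoch %d (best val %.6g)", epoch, best_val)
                break
    if best_params is not None:
        for k in param_keys:
            model.params[k] = Tensor(best_params[k], requires_grad=True)
        model.element_shifts = best_shifts
    return model, history


def train_ensemble(model_config: ModelConfig, train_frames: Sequence[LabeledFrame],
                   val_frames: Sequence[LabeledFrame],
                   loss_config: Optional[LossConfig] = None, n_members: int = 4):
    """K independently seeded fits: member k uses seed base_seed + k for both
    its parameter initialisation and its data shuffle."""
    if n_members < 1:
        raise ValueError("need at least one ensemble member")
    loss_config = loss_config or LossConfig()
    members = []
    for k in range(n_members):
        cfg_k = replace(model_config, seed=model_config.seed + k)
        loss_k = replace(loss_config, seed=loss_config.seed + k)
        member = NSEPotential(cfg_k)
        fitted, _ = train(member, train_frames, val_frames, loss_k)
        members.append(fitted)
    return members
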
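"""Joint training of encoder, predictor and decoder.

Per batch the loop draws the adversarial perturbation (one-step, treated as
constant thereafter), then takes one descent step on the combined objective

    L_Bio + λ₁·L_AFSE + λ₂·(L_Recon + L_Val)

where L_Bio is mean squared error on the pActivity scale (regression) or
cross-entropy on logits (classification), L_AFSE the prediction-stability
loss at the adversarial perturbation, L_Recon the weighted symbol
reconstruction loss, and L_Val the penalty on chemically invalid selected
substitutions. The learning rate ramps linearly to the base rate over a
warm-up fraction of steps and decays linearly to zero afterwards.

Each epoch logs the four loss components, the training-set reconstruction
and validity rates, and a validation metric (r² or accuracy on a held-out
slice of the training data); the best model is the epoch checkpoint
maximizing reconstruction rate + validity rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .afse import adversarial_perturbation_batch, afse_loss
from .agrn import reconstruction_loss, reconstruction_rate
from .autodiff import Tensor
from .encoder import GraphBatch
from .mmp import classification_metrics, regression_metrics
from .model import ModelConfig, OlbacModel
from .nn import Adam
from .optimize import (OptimizationConfig, select_key_atom, select_replacement,
                       validity_loss, PosteriorTable, resolve_eta)

__all__ = ["TrainConfig", "EpochRecord", "TrainResult", "train",
           "lr_schedule", "select_best_model", "validity_rate", "predict"]


@dataclass
class TrainConfig:
    lambda1: float = 0.6              # weight of the stabilization loss
    lambda2: float = 0.3              # weight of reconstruction + validity
    epochs: int = 100
    batch_size: int = 32
    base_lr: float = 3e-3
    warmup_fraction: float = 0.1
    seed: int = 0
    task: str = "regression"          # or "classification"
    include_bonds: bool = False
    eta: float | str = 1.0
    epsilon: float = 0.01
    p0: float = 0.5
    val_fraction: float = 0.1
    stop_at_reconstruction: float | None = None  # early stop once reached

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda coefficients must be ≥ 0")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be regression or classification")


@dataclass
class EpochRecord:
    epoch: int
    loss_bio: float
    loss_afse: float
    loss_recon: float
    loss_val: float
    reconstruction_rate: float
    validity_rate: float | None
    val_metric: float | None


@dataclass
class TrainResult:
    model: OlbacModel
    history: list[EpochRecord]
    checkpoints: list[dict] = field(repr=False, default_factory=list)


def lr_schedule(step: int, total_steps: int, base_rate: float,
                warmup_fraction: float) -> float:
    """Linear warm-up to the base rate, then linear decay to zero."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside schedule")
    warm_end = warmup_fraction * total_steps
    if warm_end > 0 and step <= warm_end:
        return base_rate * step / warm_end
    if total_steps == warm_end:
        return base_rate
    return base_rate * (total_steps - step) / (total_steps - warm_end)


def _bio_loss(pred: Tensor, y: np.ndarray, task: str) -> Tensor:
    y_t = Tensor(y[:, None])
    if task == "regression":
        return ((pred - y_t) ** 2).mean()
    p = pred.sigmoid().clamp_min(1e-12)
    q = (1.0 - pred.sigmoid()).clamp_min(1e-12)
    return -(y_t * p.log() + (1.0 - y_t) * q.log()).mean()


def _selection_for_batch(p_recon: np.ndarray, p_opt: np.ndarray,
                         batch: GraphBatch, p0: float):
    """Per-molecule (global atom index, element, Val flag) selections."""
    out = []
    offset = 0
    for g in batch.graphs:
        sl = slice(offset, offset + g.n_atoms)
        table = PosteriorTable(P_recon=p_recon[sl], P_opt=p_opt[sl])
        i_star = select_key_atom(table, p0)
        if i_star is not None:
            k_star = select_replacement(table, i_star, p0,
                                        g.atoms[i_star].symbol_index)
            if k_star is not None:
                val = chem.check_assignment_valid(g, i_star, k_star)
                out.append((offset + i_star, k_star, val,
                            float(table.P_opt[i_star, k_star])))
                offset += g.n_atoms
                continue
        out.append(None)
        offset += g.n_atoms
    return out


def _validity_penalty(p_opt_t: Tensor, selections, n_mols: int) -> Tensor:
    terms = []
    for sel in selections:
        if sel is None or sel[2] == 0:
            continue
        gi, k, _, _ = sel
        row = p_opt_t.cols(k, k + 1)
        mask = np.zeros((p_opt_t.shape[0], 1))
        mask[gi, 0] = 1.0
        p = (row * Tensor(mask)).sum()
        terms.append(-((1.0 - p).clamp_min(1e-12).log()))
    if not terms:
        return Tensor(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / n_mols)


def _epoch_rates(model: OlbacModel, batch: GraphBatch, cfg: TrainConfig,
                 rng: np.random.Generator) -> tuple[float, float | None]:
    """Training-set reconstruction and validity rates, dropout off."""
    model.eval()
    f, h = model.encoder(batch)
    recon = model.decoder.decode(f, h, batch, None, 0)
    rate = reconstruction_rate(recon.atom_probs.data, batch)
    eta = resolve_eta(cfg.eta, f.data)
    d = adversarial_perturbation_batch(f.data, model.predictor, eta,
                                       cfg.epsilon, rng)
    opt = model.decoder.decode(f, h, batch, d, 1)
    selections = _selection_for_batch(recon.atom_probs.data,
                                      opt.atom_probs.data, batch, cfg.p0)
    chosen = [s for s in selections if s is not None]
    vrate = (sum(1 for s in chosen if s[2] == 0) / len(chosen)) if chosen else None
    model.train()
    return rate, vrate


def predict(model: OlbacModel, graphs: list[chem.MolecularGraph]) -> np.ndarray:
    """Deterministic activity predictions N(f, f) (dropout off)."""
    mode = model.training
    model.eval()
    try:
        batch = GraphBatch.from_graphs(graphs)
        f, _ = model.encoder(batch)
        out = model.predictor(f, f).data[:, 0]
    finally:
        model.train(mode)
    return out


def validity_rate(model: OlbacModel, graphs: list[chem.MolecularGraph],
                  cfg: OptimizationConfig, rng: np.random.Generator) -> float | None:
    """Share of selected (i*, k*) substitutions passing the valence check;
    molecules with no candidate are excluded from the denominator. None
    when nothing was selected (never 0/0)."""
    from .optimize import posterior_tables
    chosen = 0
    valid = 0
    for g in graphs:
        table = posterior_tables(model, g, cfg, rng)
        i_star = select_key_atom(table, cfg.p0)
        if i_star is None:
            continue
        k_star = select_replacement(table, i_star, cfg.p0,
                                    g.atoms[i_star].symbol_index)
        if k_star is None:
            continue
        chosen += 1
        if not chem.check_assignment_valid(g, i_star, k_star):
            valid += 1
    return valid / chosen if chosen else None


def train(dataset: pd.DataFrame, cfg: TrainConfig,
          model_config: ModelConfig | None = None,
          invariant_hook=None) -> TrainResult:
    """Train on a (smiles, activity) table; returns the final model, the
    per-epoch history and one parameter snapshot per epoch.

    ``invariant_hook(model, batch)``, when given, runs after every descent
    step (used by the normalization test-suite).
    """
    rng = np.random.default_rng(cfg.seed)
    if model_config is None:
        model_config = ModelConfig(task=cfg.task, seed=cfg.seed)
    model = OlbacModel(model_config)
    model.train()

    graphs = [chem.parse_smiles(s) for s in dataset["smiles"]]
    y = dataset["activity"].to_numpy(dtype=float)

    n = len(graphs)
    n_val = max(int(round(cfg.val_fraction * n)), 0)
    perm = rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if len(fit_idx) == 0:
        raise ValueError("no training molecules left after validation split")
    full_batch = GraphBatch.from_graphs(graphs)
    val_graphs = [graphs[i] for i in val_idx]
    y_val = y[val_idx]

    steps_per_epoch = int(np.ceil(len(fit_idx) / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    opt = Adam(model.parameters(), lr=cfg.base_lr)

    history: list[EpochRecord] = []
    checkpoints: list[dict] = []
    step = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(fit_idx)
        sums = np.zeros(4)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = GraphBatch.from_graphs([graphs[i] for i in idx])
            yb = y[idx]

            f, h = model.encoder(batch)
            eta = resolve_eta(cfg.eta, f.data)
            d = adversarial_perturbation_batch(f.data, model.predictor, eta,
                                               cfg.epsilon, rng)
            model.zero_grad()  # probe pass must not leak into the step

            l_bio = _bio_loss(model.predictor(f, f), yb, cfg.task)
            l_afse = afse_loss(f, d, model.predictor)
            recon = model.decoder.decode(f, h, batch, None, 0)
            l_recon = reconstruction_loss(recon, include_bonds=cfg.include_bonds)
            opt_out = model.decoder.decode(f, h, batch, d, 1)
            selections = _selection_for_batch(recon.atom_probs.data,
                                              opt_out.atom_probs.data,
                                              batch, cfg.p0)
            l_val = _validity_penalty(opt_out.atom_probs, selections, batch.n_mols)

            total = l_bio + cfg.lambda1 * l_afse + cfg.lambda2 * (l_recon + l_val)
            if not np.isfinite(total.data):
                raise RuntimeError("diverged: non-finite loss; lower the "
                                   "learning rate")
            total.backward()
            step += 1
            opt.lr = lr_schedule(step, total_steps, cfg.base_lr,
                                 cfg.warmup_fraction)
            opt.step()
            model.zero_grad()
            if invariant_hook is not None:
                invariant_hook(model, batch)
            sums += [l_bio.data, l_afse.data, l_recon.data, l_val.data]

        rate, vrate = _epoch_rates(model, full_batch, cfg, rng)
        val_metric = None
        if len(val_graphs) >= 2:
            preds = predict(model, val_graphs)
            if cfg.task == "regression":
                val_metric = regression_metrics(y_val, preds)[0]
            else:
                scores = 1.0 / (1.0 + np.exp(-preds))
                val_metric = classification_metrics(y_val, scores)["acc"]
        means = sums / steps_per_epoch
        history.append(EpochRecord(epoch, *means, rate, vrate, val_metric))
        checkpoints.append(model.state_dict())
        if (cfg.stop_at_reconstruction is not None
                and rate >= cfg.stop_at_reconstruction):
            break
    return TrainResult(model=model, history=history, checkpoints=checkpoints)


def select_best_model(result: TrainResult) -> OlbacModel:
    """Checkpoint maximizing reconstruction rate + validity rate (validity
    counts 0 when not applicable); ties go to the earliest epoch."""
    if not result.history:
        raise ValueError("empty history")
    scores = [rec.reconstruction_rate + (rec.validity_rate or 0.0)
              for rec in result.history]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    model = OlbacModel(result.model.config)
    model.load_state_dict(result.checkpoints[best])
    model.eval()
    return model
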
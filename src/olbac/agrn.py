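"""Attentive graph reconstruction network (the decoder) and its losses.

Given a molecular embedding — possibly shifted by the adversarial
perturbation, ``f_in = f + s·d`` with ``s ∈ {+1, 0, −1}`` — and the atomic
embeddings ``H``, the decoder:

1. decomposes ``f_in`` onto atoms by a softmax over inner products
   (atomic responsibilities γ);
2. runs a molecule-to-atom update: ``g_i^T = γ_i·f_in + h_i``, then ``T``
   rounds of a relationship network + GRU;
3. runs ``L`` rounds of atom-to-atom attention over neighbors with edge
   states and a second GRU;
4. emits a 16-way softmax over element symbols per atom and, optionally,
   bond feature probabilities per directed edge.

``s = 0`` is the reconstruction branch (â); ``s = +1`` the optimization
branch (ã); ``s = −1`` its reverse. Zero perturbation makes all branches
identical by construction.

The reconstruction loss weights each atom's cross-entropy by
``1 − N_{K_i}/N_a`` — the share of the molecule *not* made of that atom's
element — so abundant elements (carbon, typically) do not dominate. Bond
reconstruction is off by default; symbol reconstruction is what the
optimization scheme consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .chem import BOND_FEATURE_DIM, N_SYMBOLS, MolecularGraph
from .encoder import GraphBatch
from .nn import Dropout, GRUCell, Linear, Module

__all__ = ["ReconOutput", "Decoder", "weighted_ce", "reconstruction_loss",
           "reconstruction_rate", "model_reconstruction_rate", "atom_ce_weights"]

_LOG_EPS = 1e-12


@dataclass
class ReconOutput:
    """Decoder output for a batch: row-stochastic symbol probabilities per
    atom and (optional) bond feature probabilities per directed edge."""

    atom_probs: Tensor        # (N_atoms, 16), rows on the simplex
    bond_order_probs: Tensor | None   # (N_edges, 4), rows on the simplex
    bond_flag_probs: Tensor | None    # (N_edges, 2), independent sigmoids
    gamma: Tensor             # (N_atoms, 1) atomic responsibilities
    batch: GraphBatch


class Decoder(Module):
    """AGRN with ``T`` molecule-to-atom and ``L`` atom-to-atom rounds."""

    def __init__(self, dim: int, T: int, L: int, rng: np.random.Generator,
                 dropout_p: float = 0.1, with_bonds: bool = True):
        super().__init__()
        if T < 1 or L < 1:
            raise ValueError("T and L must be ≥ 1")
        self.dim, self.T, self.L = dim, T, L
        self.dropout = Dropout(dropout_p, rng)
        self.lin_rel = Linear(2 * dim, dim, rng)       # relationship net
        self.gru_mol = GRUCell(dim, dim, rng)          # molecule-to-atom GRU
        self.lin_att = Linear(2 * dim, 1, rng)         # neighbor attention
        self.lin_ctx = Linear(dim, dim, rng)           # context map of edge states
        self.gru_atom = GRUCell(dim, dim, rng)         # atom-to-atom GRU
        self.lin_edge = Linear(2 * dim, dim, rng)      # edge state update
        self.lin_atom_out = Linear(dim, N_SYMBOLS, rng)
        self.lin_bond_out = Linear(2 * dim, BOND_FEATURE_DIM, rng) if with_bonds else None

    # ---- stages ----------------------------------------------------------

    def decompose(self, f_in: Tensor, H: Tensor, batch: GraphBatch) -> Tensor:
        """Atomic responsibilities: softmax over atoms of ⟨f_in, h_i⟩."""
        logits = (gather_rows(f_in, batch.mol_id) * H).sum(axis=1, keepdims=True)
        return segment_softmax(logits, batch.mol_id, batch.n_mols)

    def molecule_to_atom(self, f_in: Tensor, H: Tensor, gamma: Tensor,
                         batch: GraphBatch) -> Tensor:
        f_atom = gather_rows(f_in, batch.mol_id)
        g = gamma * f_atom + H
        for _ in range(self.T):
            rel = self.lin_rel(self.dropout(concat([f_atom, g]))).elu()
            g = self.gru_mol(rel, g).relu()
        return g

    def atom_to_atom(self, g: Tensor, batch: GraphBatch) -> tuple[Tensor, Tensor | None]:
        if batch.src.size == 0:
            return g, None
        g_edge = gather_rows(g, batch.src)  # edge state j→i starts from g_j
        has_nbr = Tensor((np.bincount(batch.dst, minlength=batch.n_atoms) > 0)
                         .astype(float)[:, None])
        self.last_attention = []  # (weights, dst) per round, for invariant checks
        for _ in range(self.L):
            g_dst = gather_rows(g, batch.dst)
            score = self.lin_att(self.dropout(concat([g_dst, g_edge]))).leaky_relu()
            w = segment_softmax(score, batch.dst, batch.n_atoms)
            self.last_attention.append((w.data.copy(), batch.dst))
            ctx = segment_sum(w * self.lin_ctx(self.dropout(g_edge)),
                              batch.dst, batch.n_atoms).elu()
            ctx = ctx * has_nbr  # isolated atoms keep a zero context
            g_new = self.gru_atom(ctx, g).relu()
            g_edge = self.lin_edge(self.dropout(concat([g_dst, g_edge]))).leaky_relu()
            g = g_new
        return g, g_edge

    def generate(self, g_atoms: Tensor, g_edges: Tensor | None,
                 batch: GraphBatch) -> tuple[Tensor, Tensor | None, Tensor | None]:
        atom_probs = self.lin_atom_out(g_atoms).softmax_rows()
        if self.lin_bond_out is None or g_edges is None:
            return atom_probs, None, None
        g_dst = gather_rows(g_atoms, batch.dst)
        z = self.lin_bond_out(self.dropout(concat([g_dst, g_edges]))).leaky_relu()
        order = z.cols(0, 4).softmax_rows()
        flags = z.cols(4, BOND_FEATURE_DIM).sigmoid()
        return atom_probs, order, flags

    # ---- composite -------------------------------------------------------

    def decode(self, f: Tensor, H: Tensor, batch: GraphBatch,
               d: np.ndarray | None, s: int) -> ReconOutput:
        """Full pass with ``f_in = f + s·d``; ``s=0`` reconstructs, ``s=+1``
        optimizes, ``s=−1`` reverse-optimizes. ``d`` enters as a constant."""
        if s not in (-1, 0, 1):
            raise ValueError("direction s must be −1, 0 or +1")
        if s == 0 or d is None:
            f_in = f
        else:
            f_in = f + Tensor(float(s) * np.atleast_2d(d))
        gamma = self.decompose(f_in, H, batch)
        g = self.molecule_to_atom(f_in, H, gamma, batch)
        g_atoms, g_edges = self.atom_to_atom(g, batch)
        atom_probs, order, flags = self.generate(g_atoms, g_edges, batch)
        return ReconOutput(atom_probs=atom_probs, bond_order_probs=order,
                           bond_flag_probs=flags, gamma=gamma, batch=batch)


# ---- losses --------------------------------------------------------------


def atom_ce_weights(batch: GraphBatch) -> np.ndarray:
    """Per-atom weights ``1 − N_{K_i}/N_a`` within each molecule."""
    w = np.empty(batch.n_atoms)
    offset = 0
    for g in batch.graphs:
        syms = g.symbol_indices()
        counts = np.bincount(syms, minlength=N_SYMBOLS)
        w[offset : offset + g.n_atoms] = 1.0 - counts[syms] / g.n_atoms
        offset += g.n_atoms
    return w


def weighted_ce(atom_probs: Tensor | np.ndarray, g: MolecularGraph) -> Tensor:
    """Element-weighted cross-entropy of one molecule's symbol
    reconstruction: Σ_i (1 − N_{K_i}/N_a)·(−log p̂_i[K_i])."""
    if not isinstance(atom_probs, Tensor):
        atom_probs = Tensor(atom_probs)
    batch = GraphBatch.from_graphs([g])
    return _weighted_ce_batch(atom_probs, batch).sum()


def _weighted_ce_batch(atom_probs: Tensor, batch: GraphBatch) -> Tensor:
    """(n_mols × 1) weighted symbol cross-entropy per molecule."""
    syms = np.concatenate([g.symbol_indices() for g in batch.graphs])
    onehot = np.zeros((batch.n_atoms, N_SYMBOLS))
    onehot[np.arange(batch.n_atoms), syms] = 1.0
    w = atom_ce_weights(batch)[:, None]
    ce = -(Tensor(onehot) * atom_probs.clamp_min(_LOG_EPS).log()).sum(axis=1, keepdims=True)
    return segment_sum(Tensor(w) * ce, batch.mol_id, batch.n_mols)


def _bond_ce_batch(recon: ReconOutput) -> Tensor:
    """(n_mols × 1) bond-feature cross-entropy summed over directed edges."""
    batch = recon.batch
    true_orders, true_flags, edge_mol = [], [], []
    for m, g in enumerate(batch.graphs):
        for b in g.bonds:
            row_order = np.zeros(4)
            row_order[("single", "double", "triple", "aromatic").index(b.order)] = 1.0
            for _ in range(2):  # each bond appears as two directed edges
                true_orders.append(row_order)
                true_flags.append([float(b.conjugated), float(b.in_ring)])
                edge_mol.append(m)
    to = Tensor(np.array(true_orders))
    tf = Tensor(np.array(true_flags))
    edge_mol = np.array(edge_mol, dtype=np.intp)
    ce_order = -(to * recon.bond_order_probs.clamp_min(_LOG_EPS).log()).sum(axis=1, keepdims=True)
    p = recon.bond_flag_probs.clamp_min(_LOG_EPS)
    q = (1.0 - recon.bond_flag_probs).clamp_min(_LOG_EPS)
    bce = -(tf * p.log() + (1.0 - tf) * q.log()).sum(axis=1, keepdims=True)
    return segment_sum(ce_order + bce, edge_mol, batch.n_mols)


def reconstruction_loss(recon: ReconOutput, include_bonds: bool = False) -> Tensor:
    """Mean over molecules of (1/N_a)·[weighted symbol CE + optional bond
    CE]; zero for a perfect reconstruction."""
    batch = recon.batch
    per_mol = _weighted_ce_batch(recon.atom_probs, batch)
    if include_bonds:
        if recon.bond_order_probs is None:
            raise ValueError("decoder was built without bond heads")
        per_mol = per_mol + _bond_ce_batch(recon)
    inv_na = Tensor(1.0 / batch.atom_counts().astype(float)[:, None])
    return (per_mol * inv_na).mean()


def model_reconstruction_rate(model, graphs: list[MolecularGraph]) -> float:
    """Reconstruction rate of a model over a list of molecules (dropout
    off): decode the unperturbed branch and score exact symbol recovery."""
    mode = model.training
    model.eval()
    try:
        batch = GraphBatch.from_graphs(graphs)
        f, h = model.encoder(batch)
        probs = model.decoder.decode(f, h, batch, None, 0).atom_probs.data
    finally:
        model.train(mode)
    return reconstruction_rate(probs, batch)


def reconstruction_rate(atom_probs: np.ndarray, batch: GraphBatch) -> float:
    """Fraction of molecules whose argmax symbol prediction is exact at
    every atom."""
    pred = np.asarray(atom_probs).argmax(axis=1)
    syms = np.concatenate([g.symbol_indices() for g in batch.graphs])
    ok_atom = pred == syms
    ok_mol = np.ones(batch.n_mols, dtype=bool)
    np.logical_and.at(ok_mol, batch.mol_id, ok_atom)
    return float(ok_mol.mean())
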
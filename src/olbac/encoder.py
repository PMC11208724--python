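"""Attentive message-passing encoder and the two-argument activity predictor.

The encoder follows the attentive-fingerprint recipe: per-atom states are
initialized from chemical features, then refined for ``L`` rounds of
neighbor attention (scores over incoming edges, softmax per receiving atom)
followed by a GRU state update. The molecular embedding ``f`` is the plain
sum of the final atomic embeddings, so ``f = Σ_i h_i`` exactly and the
decoder can decompose ``f`` back onto atoms.

The predictor ``N(f1, f2)`` is a two-layer feed-forward network on the
concatenation ``[f1 ∥ f2]``; bioactivity prediction uses ``N(f, f)`` and the
adversarial machinery probes ``N(f, f + r)``.

Molecules are processed as disjoint unions (:class:`GraphBatch`): atoms of a
batch are concatenated and all message passing is edge-table arithmetic with
segment reductions, which keeps training vectorized without a tensor
framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_softmax, segment_sum
from .chem import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph, featurize
from .nn import Dropout, GRUCell, Linear, Module

__all__ = ["GraphBatch", "EmbeddingPair", "Encoder", "Predictor"]


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with directed edge tables."""

    X: np.ndarray        # (N_atoms, atom feature dim)
    E: np.ndarray        # (N_edges, bond feature dim); each bond appears twice
    src: np.ndarray      # (N_edges,) source atom of each directed edge j→i
    dst: np.ndarray      # (N_edges,) receiving atom i
    mol_id: np.ndarray   # (N_atoms,) molecule index per atom
    n_mols: int
    graphs: list[MolecularGraph]

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        xs, es, srcs, dsts, mids = [], [], [], [], []
        offset = 0
        for m, g in enumerate(graphs):
            X, E = featurize(g)
            xs.append(X)
            mids.append(np.full(g.n_atoms, m, dtype=np.intp))
            for row, b in enumerate(g.bonds):
                for a, c in ((b.i, b.j), (b.j, b.i)):
                    srcs.append(a + offset)
                    dsts.append(c + offset)
                    es.append(E[row])
            offset += g.n_atoms
        return cls(
            X=np.vstack(xs),
            E=np.array(es).reshape(-1, BOND_FEATURE_DIM),
            src=np.array(srcs, dtype=np.intp),
            dst=np.array(dsts, dtype=np.intp),
            mol_id=np.concatenate(mids),
            n_mols=len(graphs),
            graphs=list(graphs),
        )

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]

    def atom_counts(self) -> np.ndarray:
        return np.bincount(self.mol_id, minlength=self.n_mols)


@dataclass
class EmbeddingPair:
    """Molecular embedding ``f`` with the atomic embeddings it sums."""

    f: np.ndarray  # (D,)
    H: np.ndarray  # (N_a, D)


class _AttentionLayer(Module):
    """One round of neighbor attention + GRU update on atom states."""

    def __init__(self, dim: int, rng: np.random.Generator, dropout: Dropout):
        super().__init__()
        self.lin_nbr = Linear(dim + BOND_FEATURE_DIM, dim, rng)
        self.lin_att = Linear(2 * dim, 1, rng)
        self.lin_ctx = Linear(dim, dim, rng)
        self.gru = GRUCell(dim, dim, rng)
        self.dropout = dropout

    def __call__(self, h: Tensor, batch: GraphBatch, e_feat: Tensor) -> Tensor:
        if batch.src.size == 0:  # single-atom molecules only: state passes through
            return h
        h_src = gather_rows(h, batch.src)
        h_dst = gather_rows(h, batch.dst)
        msg = self.lin_nbr(self.dropout(concat([h_src, e_feat]))).leaky_relu()
        score = self.lin_att(self.dropout(concat([h_dst, msg]))).leaky_relu()
        w = segment_softmax(score, batch.dst, batch.n_atoms)
        self.last_attention = (w.data.copy(), batch.dst)  # for invariant checks
        ctx = segment_sum(w * self.lin_ctx(self.dropout(msg)), batch.dst, batch.n_atoms).elu()
        # atoms with no incoming edge keep a zero context
        has_nbr = np.bincount(batch.dst, minlength=batch.n_atoms) > 0
        ctx = ctx * Tensor(has_nbr[:, None].astype(float))
        return self.gru(ctx, h).relu()


class Encoder(Module):
    """Stack of attention layers with a sum readout."""

    def __init__(self, dim: int, n_layers: int, rng: np.random.Generator,
                 dropout_p: float = 0.1):
        super().__init__()
        self.dim = dim
        self.n_layers = n_layers
        self.dropout = Dropout(dropout_p, rng)
        self.lin_in = Linear(ATOM_FEATURE_DIM, dim, rng)
        for l in range(n_layers):
            setattr(self, f"layer{l}", _AttentionLayer(dim, rng, self.dropout))

    def __call__(self, batch: GraphBatch) -> tuple[Tensor, Tensor]:
        """Return ``(f, H)``: (n_mols × D) molecular and (n_atoms × D)
        atomic embeddings, with ``f`` the exact per-molecule sum of ``H``."""
        h = self.lin_in(Tensor(batch.X)).leaky_relu()
        e_feat = Tensor(batch.E)
        for l in range(self.n_layers):
            h = getattr(self, f"layer{l}")(h, batch, e_feat)
        f = segment_sum(h, batch.mol_id, batch.n_mols)
        return f, h

    def encode(self, g: MolecularGraph) -> EmbeddingPair:
        """Deterministic single-molecule embedding (dropout off)."""
        mode = self.training
        self.eval()
        try:
            f, h = self(GraphBatch.from_graphs([g]))
        finally:
            self.train(mode)
        return EmbeddingPair(f=f.data[0].copy(), H=h.data.copy())


class Predictor(Module):
    """``N(f1, f2)``: feed-forward on the concatenated pair of embeddings.

    Emits a raw value on the pActivity scale for regression or a logit for
    classification; no output activation either way.
    """

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(2 * dim, hidden, rng)
        self.lin2 = Linear(hidden, 1, rng)

    def __call__(self, f1: Tensor, f2: Tensor) -> Tensor:
        """Row-wise prediction for (M × D) inputs; returns (M × 1)."""
        return self.lin2(self.lin1(concat([f1, f2])).relu())

    def predict_value(self, f1: np.ndarray, f2: np.ndarray) -> float:
        out = self(Tensor(np.atleast_2d(f1)), Tensor(np.atleast_2d(f2)))
        return float(out.data[0, 0])
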
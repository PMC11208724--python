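"""Matched-molecular-pair cliff mining, activity-cliff splits, discovery
matching and performance metrics.

An MMP-cliff is an ordered pair of molecules that differ at exactly one
atom's element (all bonds identical) and whose activities — on the log10
pActivity scale — differ by at least one unit (≥ 10-fold).

Splits follow the optimization protocol: in *optimization* mode the
low-activity member of every cliff stays in the training set and the high
member is held out as a discovery target; *reverse* mode mirrors this.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .chem import MolecularGraph, parse_smiles, to_canonical_smiles

__all__ = [
    "MMPCliff",
    "EvalReport",
    "single_atom_difference",
    "mine_mmp_cliffs",
    "make_ac_splits",
    "match_discovered",
    "regression_metrics",
    "classification_metrics",
    "transformation_key",
]


@dataclass(frozen=True)
class MMPCliff:
    low_smiles: str        # canonical
    high_smiles: str
    low_activity: float
    high_activity: float
    diff_atom: int         # index in the low-activity molecule
    delta: float           # high − low, log10 units

    def as_dict(self) -> dict:
        return {
            "low_smiles": self.low_smiles, "high_smiles": self.high_smiles,
            "low_activity": self.low_activity, "high_activity": self.high_activity,
            "diff_atom": self.diff_atom, "delta": self.delta,
        }


@dataclass
class EvalReport:
    n_anchor: int
    n_generated: int
    n_discovered: int
    max_pred: float | None
    mean_pred: float | None
    novel_transformations: int

    def __post_init__(self):
        assert 0 <= self.n_discovered <= self.n_generated <= self.n_anchor

    def as_dict(self) -> dict:
        return self.__dict__.copy()


# ---- single-atom difference ---------------------------------------------


def _nx_graph(g: MolecularGraph) -> nx.Graph:
    G = nx.Graph()
    for i, a in enumerate(g.atoms):
        G.add_node(i, label=(a.symbol, a.formal_charge))
    for b in g.bonds:
        G.add_edge(b.i, b.j, order=b.order)
    return G


def _label_counter(g: MolecularGraph) -> Counter:
    return Counter((a.symbol, a.formal_charge) for a in g.atoms)


def single_atom_difference(g1: MolecularGraph, g2: MolecularGraph) -> int | None:
    """Index (in ``g1``) of the single differing atom, or None.

    The molecules must have equal atom counts and identical bond
    structure under some isomorphism matching every atom label except
    exactly one position. Candidate positions are masked with a wildcard
    label and the masked graphs compared by exact isomorphism.
    """
    if g1.n_atoms != g2.n_atoms or len(g1.bonds) != len(g2.bonds):
        return None
    c1, c2 = _label_counter(g1), _label_counter(g2)
    out, inn = c1 - c2, c2 - c1
    if sum(out.values()) != 1 or sum(inn.values()) != 1:
        return None
    (lab1,), (lab2,) = out.keys(), inn.keys()
    if Counter(b.order for b in g1.bonds) != Counter(b.order for b in g2.bonds):
        return None
    G1, G2 = _nx_graph(g1), _nx_graph(g2)
    node_eq = nx.algorithms.isomorphism.categorical_node_match("label", None)
    edge_eq = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    wild = ("*", 0)
    for i in range(g1.n_atoms):
        if G1.nodes[i]["label"] != lab1:
            continue
        for j in range(g2.n_atoms):
            if G2.nodes[j]["label"] != lab2:
                continue
            old1, old2 = G1.nodes[i]["label"], G2.nodes[j]["label"]
            G1.nodes[i]["label"] = G2.nodes[j]["label"] = wild
            same = nx.is_isomorphic(G1, G2, node_match=node_eq, edge_match=edge_eq)
            G1.nodes[i]["label"], G2.nodes[j]["label"] = old1, old2
            if same:
                return i
    return None


# ---- mining and splits ---------------------------------------------------


def mine_mmp_cliffs(dataset: pd.DataFrame, fold_threshold: float = 10.0) -> list[MMPCliff]:
    """All unordered single-atom-difference pairs with an activity gap of at
    least ``log10(fold_threshold)``; deterministic and order-invariant.

    ``dataset`` needs ``smiles`` and ``activity`` columns with activities on
    the log10 (pActivity) scale.
    """
    if (dataset["activity"].abs() > 15).any():
        warnings.warn("activities exceed 15; expected log10 (pActivity) scale",
                      stacklevel=2)
    min_delta = np.log10(fold_threshold)
    entries = []
    for smi, act in zip(dataset["smiles"], dataset["activity"]):
        g = parse_smiles(smi)
        key = (g.n_atoms, tuple(sorted(b.order for b in g.bonds)))
        entries.append((to_canonical_smiles(g), float(act), g, key))
    entries.sort(key=lambda e: (e[0], e[1]))  # row-order invariance
    cliffs = []
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            s1, act1, g1, k1 = entries[a]
            s2, act2, g2, k2 = entries[b]
            if k1 != k2 or s1 == s2 or abs(act1 - act2) < min_delta:
                continue
            if act1 <= act2:
                low, high = (s1, act1, g1), (s2, act2, g2)
            else:
                low, high = (s2, act2, g2), (s1, act1, g1)
            idx = single_atom_difference(low[2], high[2])
            if idx is None:
                continue
            cliffs.append(MMPCliff(low[0], high[0], low[1], high[1], idx,
                                   high[1] - low[1]))
    return cliffs


def make_ac_splits(dataset: pd.DataFrame, cliffs: list[MMPCliff],
                   mode: str = "optimization") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (train, heldout_targets) by cliff membership.

    ``optimization``: cliff lows train, cliff highs held out; ``reverse``:
    mirrored. A molecule that is a held-out member of any cliff is excluded
    from training even if another cliff would keep it.
    """
    if mode not in ("optimization", "reverse"):
        raise ValueError("mode must be 'optimization' or 'reverse'")
    heldout_keys = {c.high_smiles if mode == "optimization" else c.low_smiles
                    for c in cliffs}
    canon = dataset["smiles"].map(lambda s: to_canonical_smiles(parse_smiles(s)))
    mask = canon.isin(heldout_keys)
    train = dataset.loc[~mask].drop_duplicates("smiles").reset_index(drop=True)
    heldout = dataset.loc[mask].drop_duplicates("smiles").reset_index(drop=True)
    return train, heldout


def match_discovered(generated: list[str], heldout_targets: list[str]) -> tuple[list[tuple[str, str]], int]:
    """Exact canonical-SMILES matches of generated molecules against
    held-out targets; returns (matched pairs, count of distinct matches)."""
    canon_targets = {to_canonical_smiles(parse_smiles(s)) for s in heldout_targets}
    pairs, seen = [], set()
    for s in generated:
        c = to_canonical_smiles(parse_smiles(s))
        if c in canon_targets:
            pairs.append((s, c))
            seen.add(c)
    return pairs, len(seen)


def transformation_key(anchor: MolecularGraph, atom_index: int,
                       new_symbol: str) -> tuple:
    """Novelty key of a single-atom transformation: the substituted atom's
    element, its first-shell environment (sorted neighbor element + bond
    order pairs), and the element it becomes."""
    env = tuple(sorted(
        (anchor.atoms[j].symbol,
         next(b.order for b in anchor.bonds
              if {b.i, b.j} == {atom_index, j}))
        for j in anchor.neighbors(atom_index)
    ))
    return (anchor.atoms[atom_index].symbol, env, new_symbol)


# ---- metrics -------------------------------------------------------------


def regression_metrics(y_true, y_pred) -> tuple[float | None, float]:
    """(r², RMSE): squared Pearson correlation and root mean square error.

    r² is None (not applicable) when either vector has zero variance.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two same-length vectors of length ≥ 2")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return None, rmse
    r = stats.pearsonr(y_true, y_pred).statistic
    return float(r * r), rmse


def classification_metrics(y_true, scores) -> dict[str, float | None]:
    """AUROC, accuracy, MCC, specificity and sensitivity for binary labels;
    probability threshold 0.5 for the confusion-matrix metrics. AUROC and
    MCC are None on single-class input."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= 0.5).astype(int)
    tn = int(np.sum((y_true == 0) & (pred == 0)))
    fp = int(np.sum((y_true == 0) & (pred == 1)))
    fn = int(np.sum((y_true == 1) & (pred == 0)))
    tp = int(np.sum((y_true == 1) & (pred == 1)))
    single_class = len(np.unique(y_true)) < 2
    return {
        "auroc": None if single_class else float(skm.roc_auc_score(y_true, scores)),
        "acc": (tp + tn) / len(y_true),
        "mcc": None if single_class else float(skm.matthews_corrcoef(y_true, pred)),
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
    }
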
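"""Molecular graphs, the 16-element vocabulary, featurization and single-atom
substitution.

Molecules are heavy-atom graphs parsed with RDKit. The element vocabulary is
the 16-symbol set used by attentive-fingerprint models — B, C, N, O, F, Si,
P, S, Cl, As, Se, Br, Te, I, At, plus a catch-all "other" — each with a
neutral-atom maximum valence. "other" is never a legal substitution target.

Validity of placing element ``k`` at atom ``i`` keeps every bond fixed and
asks whether the atom's explicit valence (aromatic bonds counted 1.5,
rounded up) fits under ``max_valence(k)``; formal charges are preserved and
charged anchors that the neutral-valence rule cannot justify are simply
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse errors are reported via exceptions

__all__ = [
    "ELEMENTS",
    "MAX_VALENCE",
    "OTHER_INDEX",
    "N_SYMBOLS",
    "AtomRecord",
    "BondRecord",
    "MolecularGraph",
    "parse_smiles",
    "to_canonical_smiles",
    "featurize",
    "check_assignment_valid",
    "substitute_atom",
    "read_molecule_csv",
    "read_molecule_sdf",
    "write_results_csv",
    "ATOM_FEATURE_DIM",
    "BOND_FEATURE_DIM",
]

# 16-way element vocabulary; index order is the symbol index k = 0..15.
ELEMENTS: tuple[str, ...] = (
    "B", "C", "N", "O", "F", "Si", "P", "S",
    "Cl", "As", "Se", "Br", "Te", "I", "At", "other",
)
MAX_VALENCE: dict[str, int] = {
    "B": 3, "C": 4, "N": 3, "O": 2, "F": 1, "Si": 4, "P": 5, "S": 6,
    "Cl": 1, "As": 5, "Se": 6, "Br": 1, "Te": 6, "I": 1, "At": 1, "other": 4,
}
N_SYMBOLS = len(ELEMENTS)
OTHER_INDEX = ELEMENTS.index("other")
_SYMBOL_TO_INDEX = {s: i for i, s in enumerate(ELEMENTS)}

_BOND_ORDERS = ("single", "double", "triple", "aromatic")
_BOND_VALENCE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

ATOM_FEATURE_DIM = N_SYMBOLS + 6 + 1 + 1 + 5  # symbol, degree 0-5, charge, aromatic, implicit H 0-4
BOND_FEATURE_DIM = 4 + 1 + 1  # order one-hot, conjugated, in-ring


class ChemError(ValueError):
    """Raised for unparseable, unsupported, or valence-violating molecules."""


@dataclass(frozen=True)
class AtomRecord:
    symbol_index: int
    formal_charge: int
    explicit_valence: float  # sum of bond orders, aromatic = 1.5
    implicit_h: int
    is_aromatic: bool

    @property
    def symbol(self) -> str:
        return ELEMENTS[self.symbol_index]


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    order: str  # single / double / triple / aromatic
    in_ring: bool
    conjugated: bool


@dataclass(frozen=True)
class MolecularGraph:
    """Single-fragment heavy-atom graph; the unit of reconstruction and
    optimization."""

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]
    adjacency: tuple[tuple[int, ...], ...] = field(compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> tuple[int, ...]:
        return self.adjacency[i]

    def symbol_indices(self) -> np.ndarray:
        return np.array([a.symbol_index for a in self.atoms], dtype=np.intp)


def _build_adjacency(n: int, bonds) -> tuple[tuple[int, ...], ...]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    return tuple(tuple(sorted(a)) for a in adj)


def _from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ChemError("multi-fragment molecule: expected a single fragment")
    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        idx = _SYMBOL_TO_INDEX.get(sym)
        if idx is None:
            raise ChemError(f"unsupported element: {sym}")
        ev = sum(_BOND_VALENCE[_bond_order_label(b)] for b in a.GetBonds())
        atoms.append(
            AtomRecord(
                symbol_index=idx,
                formal_charge=a.GetFormalCharge(),
                explicit_valence=ev,
                implicit_h=a.GetTotalNumHs(),
                is_aromatic=a.GetIsAromatic(),
            )
        )
    bonds = tuple(
        BondRecord(
            i=b.GetBeginAtomIdx(),
            j=b.GetEndAtomIdx(),
            order=_bond_order_label(b),
            in_ring=b.IsInRing(),
            conjugated=b.GetIsConjugated(),
        )
        for b in mol.GetBonds()
    )
    return MolecularGraph(tuple(atoms), bonds, _build_adjacency(len(atoms), bonds))


def _bond_order_label(b: Chem.Bond) -> str:
    t = b.GetBondType()
    if t == Chem.BondType.SINGLE:
        return "single"
    if t == Chem.BondType.DOUBLE:
        return "double"
    if t == Chem.BondType.TRIPLE:
        return "triple"
    if t == Chem.BondType.AROMATIC:
        return "aromatic"
    raise ChemError(f"unsupported bond type: {t}")


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph.

    Stereochemistry is discarded; implicit hydrogens are recorded per atom.
    Raises :class:`ChemError` for unparseable input, out-of-vocabulary
    elements, or multi-fragment molecules.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return _from_rdkit(mol)


def to_rdkit(g: MolecularGraph) -> Chem.Mol:
    """Rebuild a sanitized RDKit molecule from the graph."""
    em = Chem.RWMol()
    for a in g.atoms:
        if a.symbol == "other":
            raise ChemError('cannot serialize the placeholder element "other"')
        ra = Chem.Atom(a.symbol)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.implicit_h)
        ra.SetNoImplicit(True)
        ra.SetIsAromatic(a.is_aromatic)
        em.AddAtom(ra)
    bt = {
        "single": Chem.BondType.SINGLE,
        "double": Chem.BondType.DOUBLE,
        "triple": Chem.BondType.TRIPLE,
        "aromatic": Chem.BondType.AROMATIC,
    }
    for b in g.bonds:
        em.AddBond(b.i, b.j, bt[b.order])
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types
        raise ChemError(f"unsanitizable molecule: {exc}") from exc
    return mol


def to_canonical_smiles(g: MolecularGraph) -> str:
    """Canonical SMILES; equal iff the graphs are identical up to relabeling."""
    return Chem.MolToSmiles(to_rdkit(g))


def featurize(g: MolecularGraph) -> tuple[np.ndarray, np.ndarray]:
    """Atom and bond feature matrices.

    Atom rows: ``[symbol one-hot (16) | degree one-hot (0..5) | formal
    charge | aromatic flag | implicit-H one-hot (0..4)]``. Bond rows:
    ``[order one-hot (4) | conjugated | in-ring]``, one row per bond in
    ``g.bonds`` order.
    """
    X = np.zeros((g.n_atoms, ATOM_FEATURE_DIM))
    for i, a in enumerate(g.atoms):
        X[i, a.symbol_index] = 1.0
        X[i, N_SYMBOLS + min(len(g.adjacency[i]), 5)] = 1.0
        X[i, N_SYMBOLS + 6] = a.formal_charge
        X[i, N_SYMBOLS + 7] = float(a.is_aromatic)
        X[i, N_SYMBOLS + 8 + min(a.implicit_h, 4)] = 1.0
    E = np.zeros((len(g.bonds), BOND_FEATURE_DIM))
    for r, b in enumerate(g.bonds):
        E[r, _BOND_ORDERS.index(b.order)] = 1.0
        E[r, 4] = float(b.conjugated)
        E[r, 5] = float(b.in_ring)
    return X, E


def _substituted(g: MolecularGraph, i: int, k: int) -> MolecularGraph:
    """Relabel atom ``i`` to element ``k`` with bonds untouched.

    The new atom's implicit hydrogen count is re-derived by RDKit's
    default-valence model (so O→S on ethanol yields CCS, not a
    hexavalent sulfur), and the whole molecule is re-sanitized; a
    :class:`ChemError` propagates if the relabeled molecule is not
    chemically sound."""
    mol = Chem.RWMol(to_rdkit(g))
    a = mol.GetAtomWithIdx(i)
    a.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(ELEMENTS[k]))
    a.SetNumExplicitHs(0)
    a.SetNoImplicit(False)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise ChemError(f"unsanitizable molecule: {exc}") from exc
    new = _from_rdkit(out)
    # a pure relabeling must leave every bond untouched; re-perception that
    # alters bond orders (e.g. breaking aromaticity) is not a valid relabel
    if [(b.i, b.j, b.order) for b in new.bonds] != \
       [(b.i, b.j, b.order) for b in g.bonds]:
        raise ChemError("substitution would alter bond orders")
    return new


def check_assignment_valid(g: MolecularGraph, i: int, k: int) -> int:
    """Mask value Val(k|i): 1 if placing element ``k`` at atom ``i`` is
    chemically invalid with all bonds kept, else 0.

    The current element is always a valid (identity) assignment; the
    placeholder "other" is always invalid as a target. Candidates passing
    the neutral-atom valence arithmetic are confirmed by full sanitization
    of the substituted molecule, so aromatic systems and charged anchors
    that the arithmetic cannot judge are handled conservatively.
    """
    if not (0 <= i < g.n_atoms) or not (0 <= k < N_SYMBOLS):
        raise IndexError("atom or symbol index out of range")
    atom = g.atoms[i]
    if k == atom.symbol_index:
        return 0
    if k == OTHER_INDEX:
        return 1
    if ceil(atom.explicit_valence) > MAX_VALENCE[ELEMENTS[k]]:
        return 1
    try:
        _substituted(g, i, k)
    except ChemError:
        return 1
    return 0


def substitute_atom(g: MolecularGraph, i: int, k: int) -> MolecularGraph:
    """Return a copy of ``g`` with atom ``i`` relabeled to element ``k``.

    Bonds are untouched. Raises :class:`ChemError` on a valence violation.
    """
    if check_assignment_valid(g, i, k):
        raise ChemError(
            f"valence violation: cannot place {ELEMENTS[k]} at atom {i}"
        )
    if k == g.atoms[i].symbol_index:
        return g
    return _substituted(g, i, k)


# ---- dataset I/O ---------------------------------------------------------


def read_molecule_csv(path, activity_column: str | None = None) -> pd.DataFrame:
    """Read a `smiles,<activity>` CSV; returns columns ``smiles``/``activity``.

    Every SMILES must parse within the element vocabulary as a single
    fragment; offending rows raise with their row number.
    """
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise ChemError(f"{path}: missing required column 'smiles'")
    if activity_column is None:
        candidates = [c for c in df.columns if c != "smiles"]
        if not candidates:
            raise ChemError(f"{path}: no activity column found")
        activity_column = candidates[0]
    out = df[["smiles", activity_column]].rename(columns={activity_column: "activity"})
    for row, smi in enumerate(out["smiles"]):
        try:
            parse_smiles(smi)
        except ChemError as exc:
            raise ChemError(f"{path} row {row}: {exc}") from exc
    return out


def read_molecule_sdf(path) -> pd.DataFrame:
    """Read an SDF (connectivity only; conformers ignored) into a table of
    canonical SMILES."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    smiles = []
    for idx, mol in enumerate(supplier):
        if mol is None:
            raise ChemError(f"{path}: unparseable record {idx}")
        Chem.RemoveStereochemistry(mol)
        smiles.append(Chem.MolToSmiles(mol))
    return pd.DataFrame({"smiles": smiles})


def write_results_csv(path, rows: list[dict]) -> None:
    """Write optimization results with the canonical column schema."""
    cols = [
        "anchor_smiles", "optimized_smiles", "atom_index",
        "old_symbol", "new_symbol", "confidence", "status",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
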
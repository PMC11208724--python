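"""Synthetic molecule libraries with a planted element-at-site
structure–activity rule.

Each scaffold is a random aliphatic carbon skeleton (chain or ring, 4–12
carbons, 0–2 methyl decorations) with one marked substitution site: a
terminal heteroatom bonded to a skeleton carbon. Variants of a scaffold
place different elements at the site, and the activity is

    activity = base(scaffold) + effect(site element) + N(0, σ).

Scaffolds are deduplicated on their site-masked canonical form, so two
molecules differ at exactly one atom **iff** they are variants of the same
scaffold — the planted cliff list is therefore exhaustive, and with σ = 0
the mined cliff set equals it exactly.

A scaffold can also emit a single variant ("singleton", controlled by
``singleton_fraction``): singletons span the activity range without forming
pairs, providing background structure–activity signal — in particular
high-activity examples of the favorable element — while every paired
scaffold contributes true MMP-cliffs whose high member an activity-cliff
split holds out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import parse_smiles
from .mmp import MMPCliff, single_atom_difference

__all__ = ["FixtureConfig", "generate_fixture", "generate_classification_fixture"]


@dataclass
class FixtureConfig:
    n_scaffolds: int = 50
    site_elements: tuple[str, ...] = ("O", "S")
    effects: dict[str, float] = field(default_factory=lambda: {"O": 0.0, "S": 2.0})
    base_range: tuple[float, float] = (5.0, 7.0)
    noise_sigma: float = 0.2
    singleton_fraction: float = 0.0   # share of scaffolds emitting one variant
    seed: int = 0

    def __post_init__(self):
        if len(self.site_elements) < 2:
            raise ValueError("need at least two site elements")
        effs = [self.effects[e] for e in self.site_elements]
        if max(effs) - min(effs) < 1.0:
            raise ValueError("effect gap must be ≥ 1 log unit so cliffs exist")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")


def _random_skeleton(rng: np.random.Generator) -> Chem.RWMol:
    """Chain or ring of 4–12 carbons with 0–2 methyl decorations."""
    n = int(rng.integers(4, 13))
    mol = Chem.RWMol()
    for _ in range(n):
        mol.AddAtom(Chem.Atom(6))
    for i in range(n - 1):
        mol.AddBond(i, i + 1, Chem.BondType.SINGLE)
    if n >= 5 and rng.random() < 0.4:
        ring = int(rng.integers(5, min(n, 6) + 1))
        mol.AddBond(0, ring - 1, Chem.BondType.SINGLE)
    for _ in range(int(rng.integers(0, 3))):
        at = int(rng.integers(0, mol.GetNumAtoms()))
        if mol.GetAtomWithIdx(at).GetDegree() <= 2:
            c = mol.AddAtom(Chem.Atom(6))
            mol.AddBond(at, c, Chem.BondType.SINGLE)
    return mol


def _make_scaffold(rng: np.random.Generator) -> tuple[str, str] | None:
    """Returns (masked canonical key, template SMILES with [At] site) or
    None when the draw is unusable."""
    mol = _random_skeleton(rng)
    anchors = [a.GetIdx() for a in mol.GetAtoms() if a.GetDegree() <= 3]
    if not anchors:
        return None
    site_at = int(anchors[rng.integers(0, len(anchors))])
    s = mol.AddAtom(Chem.Atom(0))  # wildcard marks the variable site
    mol.AddBond(site_at, s, Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    key = Chem.MolToSmiles(out)
    return key, key  # template keeps the '*' placeholder


def _variant_smiles(template: str, element: str) -> str:
    mol = Chem.MolFromSmiles(template)
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(element))
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_fixture(cfg: FixtureConfig) -> tuple[pd.DataFrame, list[MMPCliff]]:
    """Deterministic dataset (smiles, activity) plus the planted cliff list.

    Every same-scaffold variant pair with an effect gap ≥ 1 log unit is a
    ground-truth cliff (ordered low → high by planted effect). Singleton
    scaffolds contribute one variant, drawn uniformly from the site
    elements, and no cliffs.
    """
    rng = np.random.default_rng(cfg.seed)
    templates: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(templates) < cfg.n_scaffolds:
        attempts += 1
        if attempts > 200 * cfg.n_scaffolds:
            raise RuntimeError("scaffold grammar failed to produce enough "
                               "distinct scaffolds")
        made = _make_scaffold(rng)
        if made is None or made[0] in seen:
            continue
        seen.add(made[0])
        templates.append(made[1])

    n_single = int(round(cfg.singleton_fraction * cfg.n_scaffolds))
    singleton = np.zeros(cfg.n_scaffolds, dtype=bool)
    if n_single:
        singleton[rng.choice(cfg.n_scaffolds, size=n_single, replace=False)] = True

    rows, cliffs = [], []
    for t_idx, template in enumerate(templates):
        base = rng.uniform(*cfg.base_range)
        elements = (
            [cfg.site_elements[rng.integers(len(cfg.site_elements))]]
            if singleton[t_idx] else list(cfg.site_elements)
        )
        variant: dict[str, tuple[str, float]] = {}
        for elem in elements:
            smi = _variant_smiles(template, elem)
            act = base + cfg.effects[elem] + rng.normal(0.0, cfg.noise_sigma)
            rows.append({"smiles": smi, "activity": act})
            variant[elem] = (smi, act)
        for a in range(len(elements)):
            for b in range(a + 1, len(elements)):
                e1, e2 = elements[a], elements[b]
                if abs(cfg.effects[e1] - cfg.effects[e2]) < 1.0:
                    continue
                lo, hi = (e1, e2) if cfg.effects[e1] < cfg.effects[e2] else (e2, e1)
                g_lo, g_hi = parse_smiles(variant[lo][0]), parse_smiles(variant[hi][0])
                idx = single_atom_difference(g_lo, g_hi)
                cliffs.append(MMPCliff(
                    low_smiles=variant[lo][0], high_smiles=variant[hi][0],
                    low_activity=variant[lo][1], high_activity=variant[hi][1],
                    diff_atom=idx, delta=variant[hi][1] - variant[lo][1],
                ))
    return pd.DataFrame(rows), cliffs


def generate_classification_fixture(cfg: FixtureConfig) -> tuple[pd.DataFrame, list[MMPCliff]]:
    """As :func:`generate_fixture` but with binary labels: 1 iff the
    planted activity reaches the median of the generated activities."""
    df, cliffs = generate_fixture(cfg)
    thr = df["activity"].median()
    out = df.copy()
    out["activity"] = (out["activity"] >= thr).astype(int)
    return out, cliffs
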
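"""Shared fixtures: the planted-rule dataset, its activity-cliff split, and
session-scoped trained models reused across test modules.

The study dataset is 200 molecules from 135 scaffolds: 65 scaffolds emit an
O/S variant pair (a true MMP-cliff, planted effect gap 2 log units) and 70
emit a single variant, providing background signal for the favorable
element. Activity noise is σ = 0.2 log units.
"""

from __future__ import annotations

import numpy as np
import pytest

from olbac import chem, mmp
from olbac.chem import MolecularGraph
from olbac.model import ModelConfig
from olbac.synthetic import FixtureConfig, generate_fixture
from olbac.training import TrainConfig, TrainResult, train

N_SEEDS = 5
STUDY_FIXTURE = FixtureConfig(
    n_scaffolds=135,
    noise_sigma=0.2,
    singleton_fraction=70 / 135,
    seed=3,
)


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel atoms of a graph by a permutation (perm[i] = new index)."""
    from dataclasses import replace

    atoms = [None] * g.n_atoms
    for i, a in enumerate(g.atoms):
        atoms[perm[i]] = a
    bonds = tuple(
        replace(b, i=min(perm[b.i], perm[b.j]), j=max(perm[b.i], perm[b.j]))
        for b in g.bonds
    )
    adj: list[list[int]] = [[] for _ in range(g.n_atoms)]
    for b in bonds:
        adj[b.i].append(b.j)
        adj[b.j].append(b.i)
    return MolecularGraph(tuple(atoms), bonds, tuple(tuple(sorted(a)) for a in adj))


@pytest.fixture(scope="session")
def study_data():
    """Dataset, planted cliffs, mined cliffs and the optimization-mode split."""
    df, truth = generate_fixture(STUDY_FIXTURE)
    mined = mmp.mine_mmp_cliffs(df)
    train_df, heldout_df = mmp.make_ac_splits(df, mined, "optimization")
    return {
        "df": df,
        "truth": truth,
        "mined": mined,
        "train": train_df,
        "heldout": heldout_df,
    }


def _train_runs(dataset, seeds, **overrides) -> dict[int, TrainResult]:
    runs = {}
    for seed in seeds:
        tc = TrainConfig(epochs=100, seed=seed, **overrides)
        runs[seed] = train(dataset, tc, ModelConfig(seed=seed))
    return runs


@pytest.fixture(scope="session")
def split_trainings(study_data) -> dict[int, TrainResult]:
    """Five seeds trained with the full objective on the AC-split training
    set (anchor lows + background)."""
    return _train_runs(study_data["train"], range(N_SEEDS))


@pytest.fixture(scope="session")
def full_trainings(study_data) -> dict[int, TrainResult]:
    """Five seeds trained with the full objective on the complete
    200-molecule fixture (reconstruction-convergence conditions); each run
    stops once symbol reconstruction is essentially perfect."""
    return _train_runs(study_data["df"], range(N_SEEDS),
                       stop_at_reconstruction=0.99)
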
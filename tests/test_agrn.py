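"""Decoder stages, reconstruction losses and their closed forms."""

import numpy as np
import pytest

from olbac import agrn
from olbac.autodiff import Tensor
from olbac.chem import N_SYMBOLS, parse_smiles
from olbac.encoder import GraphBatch
from olbac.model import ModelConfig, OlbacModel

from conftest import permute_graph


@pytest.fixture(scope="module")
def model():
    return OlbacModel(ModelConfig(hidden_dim=16, predictor_hidden=16, seed=0)).eval()


def _embed(model, graphs):
    batch = GraphBatch.from_graphs(graphs)
    f, h = model.encoder(batch)
    return batch, f, h


class TestDecompose:
    def test_equal_inner_products_give_uniform_responsibilities(self, model):
        batch = GraphBatch.from_graphs([parse_smiles("CCCC")])
        f_in = Tensor(np.ones((1, 2)))
        H = Tensor(np.tile([0.3, 0.4], (4, 1)))
        gamma = model.decoder.decompose(f_in, H, batch)
        np.testing.assert_allclose(gamma.data[:, 0], 0.25, atol=1e-12)

    def test_hand_computed_softmax(self, model):
        """Inner products (0, ln2, ln4) → responsibilities (1/7, 2/7, 4/7)."""
        batch = GraphBatch.from_graphs([parse_smiles("CCO")])
        f_in = Tensor(np.array([[1.0]]))
        H = Tensor(np.array([[0.0], [np.log(2)], [np.log(4)]]))
        gamma = model.decoder.decompose(f_in, H, batch)
        np.testing.assert_allclose(gamma.data[:, 0], [1 / 7, 2 / 7, 4 / 7],
                                   atol=1e-12)

    def test_responsibilities_sum_to_one_per_molecule(self, model):
        graphs = [parse_smiles(s) for s in ["CCO", "c1ccccc1", "C"]]
        batch, f, h = _embed(model, graphs)
        gamma = model.decoder.decompose(f, h, batch)
        sums = np.bincount(batch.mol_id, weights=gamma.data[:, 0])
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestStages:
    def test_molecule_to_atom_outputs_nonnegative(self, model):
        graphs = [parse_smiles("CCOC"), parse_smiles("CCS")]
        batch, f, h = _embed(model, graphs)
        gamma = model.decoder.decompose(f, h, batch)
        g = model.decoder.molecule_to_atom(f, h, gamma, batch)
        assert (g.data >= 0).all()

    def test_single_neighbor_attention_weight_is_one(self, model):
        batch, f, h = _embed(model, [parse_smiles("CC")])
        recon = model.decoder.decode(f, h, batch, None, 0)
        for w, dst in model.decoder.last_attention:
            np.testing.assert_allclose(w[:, 0], 1.0, atol=1e-12)

    def test_attention_neighborhoods_sum_to_one(self, model):
        graphs = [parse_smiles(s) for s in ["c1ccccc1", "CC(C)CO"]]
        batch, f, h = _embed(model, graphs)
        model.decoder.decode(f, h, batch, None, 0)
        att = model.decoder.last_attention
        assert len(att) == model.decoder.L  # one attention round per layer
        for w, dst in att:
            sums = np.bincount(dst, weights=w[:, 0], minlength=batch.n_atoms)
            has_nbr = np.bincount(dst, minlength=batch.n_atoms) > 0
            np.testing.assert_allclose(sums[has_nbr], 1.0, atol=1e-9)

    def test_atom_probability_rows_on_simplex(self, model):
        graphs = [parse_smiles(s) for s in ["CCO", "c1ccncc1"]]
        batch, f, h = _embed(model, graphs)
        out = model.decoder.decode(f, h, batch, None, 0)
        probs = out.atom_probs.data
        assert probs.shape == (batch.n_atoms, N_SYMBOLS)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs > 0).all()

    def test_single_atom_molecule_decodes(self, model):
        batch, f, h = _embed(model, [parse_smiles("C")])
        out = model.decoder.decode(f, h, batch, None, 0)
        assert out.atom_probs.shape == (1, N_SYMBOLS)
        np.testing.assert_allclose(out.atom_probs.data.sum(), 1.0, atol=1e-9)


class TestDecode:
    def test_zero_perturbation_identical_to_reconstruction(self, model):
        graphs = [parse_smiles(s) for s in ["CCO", "c1ccccc1", "CC(C)S"]]
        batch, f, h = _embed(model, graphs)
        a = model.decoder.decode(f, h, batch, None, 0)
        b = model.decoder.decode(f, h, batch, np.zeros(f.shape), +1)
        np.testing.assert_array_equal(a.atom_probs.data, b.atom_probs.data)

    def test_forward_and_reverse_branches_differ(self, model):
        graphs = [parse_smiles("CCOC")]
        batch, f, h = _embed(model, graphs)
        rng = np.random.default_rng(0)
        d = rng.standard_normal(f.shape)
        fwd = model.decoder.decode(f, h, batch, d, +1)
        rev = model.decoder.decode(f, h, batch, d, -1)
        assert np.abs(fwd.atom_probs.data - rev.atom_probs.data).max() > 1e-8

    def test_eval_mode_deterministic(self, model):
        batch, f, h = _embed(model, [parse_smiles("CCO")])
        a = model.decoder.decode(f, h, batch, None, 0).atom_probs.data
        b = model.decoder.decode(f, h, batch, None, 0).atom_probs.data
        np.testing.assert_array_equal(a, b)

    def test_invalid_direction_rejected(self, model):
        batch, f, h = _embed(model, [parse_smiles("CCO")])
        with pytest.raises(ValueError):
            model.decoder.decode(f, h, batch, np.zeros(f.shape), 2)

    def test_equivariance_under_atom_relabeling(self, model):
        g = parse_smiles("CC(=O)OC1CCCCC1")
        rng = np.random.default_rng(1)
        perm = rng.permutation(g.n_atoms)
        gp = permute_graph(g, perm)
        b1, f1, h1 = _embed(model, [g])
        b2, f2, h2 = _embed(model, [gp])
        p1 = model.decoder.decode(f1, h1, b1, None, 0).atom_probs.data
        p2 = model.decoder.decode(f2, h2, b2, None, 0).atom_probs.data
        np.testing.assert_allclose(p2[perm], p1, atol=1e-9)


class TestLosses:
    def test_homogeneous_molecule_has_zero_weighted_ce(self):
        g = parse_smiles("CCCC")  # every weight 1 − 4/4 = 0
        probs = np.full((4, N_SYMBOLS), 1.0 / N_SYMBOLS)
        assert agrn.weighted_ce(probs, g).data == 0.0

    def test_perfect_prediction_zero_loss(self):
        g = parse_smiles("CCO")
        probs = np.zeros((3, N_SYMBOLS))
        for i, a in enumerate(g.atoms):
            probs[i, a.symbol_index] = 1.0
        assert agrn.weighted_ce(probs, g).data == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_uniform_prediction_closed_form(self):
        """C–O with uniform rows: each weight 1/2, CE = ln 16 per atom, so
        the weighted CE is exactly ln 16."""
        g = parse_smiles("CO")
        probs = np.full((2, N_SYMBOLS), 1.0 / N_SYMBOLS)
        assert agrn.weighted_ce(probs, g).data == pytest.approx(np.log(16), abs=1e-9)

    def test_reconstruction_loss_zero_when_perfect(self, model):
        graphs = [parse_smiles("CCO"), parse_smiles("CCS")]
        batch, f, h = _embed(model, graphs)
        out = model.decoder.decode(f, h, batch, None, 0)
        syms = np.concatenate([g.symbol_indices() for g in graphs])
        perfect = np.zeros_like(out.atom_probs.data)
        perfect[np.arange(len(syms)), syms] = 1.0
        out.atom_probs = Tensor(perfect)
        assert agrn.reconstruction_loss(out).data == pytest.approx(0.0, abs=1e-9)

    def test_bond_term_optional(self, model):
        graphs = [parse_smiles("CCO")]
        batch, f, h = _embed(model, graphs)
        out = model.decoder.decode(f, h, batch, None, 0)
        atom_only = agrn.reconstruction_loss(out, include_bonds=False)
        with_bonds = agrn.reconstruction_loss(out, include_bonds=True)
        assert with_bonds.data > atom_only.data


class TestReconstructionRate:
    def test_model_level_rate_matches_manual(self, model):
        graphs = [parse_smiles(s) for s in ["CCO", "CCS", "CCN"]]
        batch, f, h = _embed(model, graphs)
        probs = model.decoder.decode(f, h, batch, None, 0).atom_probs.data
        assert (agrn.model_reconstruction_rate(model, graphs)
                == agrn.reconstruction_rate(probs, batch))

    def test_perfect_model_rate_one(self):
        graphs = [parse_smiles("CCO"), parse_smiles("CCS")]
        batch = GraphBatch.from_graphs(graphs)
        syms = np.concatenate([g.symbol_indices() for g in graphs])
        probs = np.zeros((batch.n_atoms, N_SYMBOLS))
        probs[np.arange(len(syms)), syms] = 1.0
        assert agrn.reconstruction_rate(probs, batch) == 1.0

    def test_untrained_model_near_chance(self, model):
        graphs = [parse_smiles(s) for s in
                  ["CCO", "CCS", "CCN", "OCCO", "c1ccncc1", "CP", "CBr", "CCl"]]
        batch, f, h = _embed(model, graphs)
        probs = model.decoder.decode(f, h, batch, None, 0).atom_probs.data
        assert agrn.reconstruction_rate(probs, batch) < 0.5

    def test_rate_invariant_to_dataset_order(self, model):
        graphs = [parse_smiles(s) for s in ["CCO", "CCS", "CCN"]]
        batch, f, h = _embed(model, graphs)
        probs = model.decoder.decode(f, h, batch, None, 0).atom_probs.data
        r1 = agrn.reconstruction_rate(probs, batch)
        rev = graphs[::-1]
        batch2, f2, h2 = _embed(model, rev)
        probs2 = model.decoder.decode(f2, h2, batch2, None, 0).atom_probs.data
        assert agrn.reconstruction_rate(probs2, batch2) == r1
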
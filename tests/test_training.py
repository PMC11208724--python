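"""Training loop, schedule, best-model rule and training diagnostics."""

import dataclasses

import numpy as np
import pytest

from olbac import chem
from olbac.model import ModelConfig
from olbac.optimize import OptimizationConfig
from olbac.synthetic import FixtureConfig, generate_fixture
from olbac.training import (EpochRecord, TrainConfig, TrainResult, lr_schedule,
                            predict, select_best_model, train, validity_rate)

SMALL_MODEL = ModelConfig(hidden_dim=16, predictor_hidden=16, seed=0)


@pytest.fixture(scope="module")
def small_dataset():
    df, _ = generate_fixture(FixtureConfig(n_scaffolds=25, seed=11))
    return df  # 50 molecules


class TestSchedule:
    def test_starts_at_zero(self):
        assert lr_schedule(0, 100, 1e-3, 0.1) == 0.0

    def test_base_rate_at_warmup_end(self):
        assert lr_schedule(10, 100, 1e-3, 0.1) == pytest.approx(1e-3)

    def test_zero_at_the_end(self):
        assert lr_schedule(100, 100, 1e-3, 0.1) == 0.0

    def test_piecewise_linear_shape(self):
        up = [lr_schedule(s, 100, 1.0, 0.2) for s in range(0, 21)]
        down = [lr_schedule(s, 100, 1.0, 0.2) for s in range(20, 101)]
        assert up == sorted(up) and down == sorted(down, reverse=True)

    def test_out_of_range_step_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(101, 100, 1e-3, 0.1)


class TestConfig:
    def test_default_balance_coefficients(self):
        cfg = TrainConfig()
        assert cfg.lambda1 == 0.6 and cfg.lambda2 == 0.3

    def test_negative_lambdas_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda1=-0.1)


class TestTrainLoop:
    def test_smoke_run_writes_history(self, small_dataset):
        res = train(small_dataset, TrainConfig(epochs=2, seed=0), SMALL_MODEL)
        assert len(res.history) == 2
        assert len(res.checkpoints) == 2
        assert all(isinstance(r, EpochRecord) for r in res.history)

    def test_same_seed_reproduces_history(self, small_dataset):
        cfg = TrainConfig(epochs=2, seed=4)
        a = train(small_dataset, cfg, SMALL_MODEL)
        b = train(small_dataset, cfg, SMALL_MODEL)
        for ra, rb in zip(a.history, b.history):
            assert ra == rb

    def test_bio_loss_decreases_early(self, small_dataset):
        """The prediction loss drops over the first epochs for most seeds."""
        wins = 0
        for seed in range(3):
            res = train(small_dataset, TrainConfig(epochs=8, seed=seed), SMALL_MODEL)
            losses = [r.loss_bio for r in res.history]
            if losses[-1] < losses[0]:
                wins += 1
        assert wins >= 2

    def test_objective_reduces_to_bio_when_lambdas_zero(self, small_dataset):
        res = train(small_dataset,
                    TrainConfig(epochs=1, seed=0, lambda1=0.0, lambda2=0.0),
                    SMALL_MODEL)
        rec = res.history[0]
        # components are still logged; they simply get zero weight
        assert rec.loss_bio > 0 and rec.loss_recon > 0

    def test_validity_rate_bounds(self, small_dataset, study_data, split_trainings):
        model = split_trainings[0].model
        graphs = [chem.parse_smiles(s) for s in study_data["train"].smiles[:20]]
        rate = validity_rate(model, graphs, OptimizationConfig(eta="auto"),
                            np.random.default_rng(0))
        assert rate is None or 0.0 <= rate <= 1.0


class TestBestModel:
    def _result(self, rates):
        history = [EpochRecord(i + 1, 0, 0, 0, 0, rr, vr, None)
                   for i, (rr, vr) in enumerate(rates)]
        model_cfg = SMALL_MODEL
        from olbac.model import OlbacModel
        model = OlbacModel(model_cfg)
        checkpoints = []
        for i in range(len(rates)):
            sd = model.state_dict()
            # make checkpoints distinguishable
            key = next(iter(sd))
            sd[key] = sd[key] + i
            checkpoints.append(sd)
        return TrainResult(model=model, history=history, checkpoints=checkpoints), key

    def test_highest_sum_wins(self):
        res, key = self._result([(0.5, 0.5), (0.9, 0.8), (0.95, 0.6)])
        best = select_best_model(res)
        np.testing.assert_array_equal(best.state_dict()[key],
                                      res.checkpoints[1][key])

    def test_single_epoch(self):
        res, key = self._result([(0.3, None)])
        best = select_best_model(res)
        np.testing.assert_array_equal(best.state_dict()[key],
                                      res.checkpoints[0][key])

    def test_monotone_rates_pick_last(self):
        res, key = self._result([(0.2, 0.1), (0.5, 0.5), (0.9, 0.9)])
        best = select_best_model(res)
        np.testing.assert_array_equal(best.state_dict()[key],
                                      res.checkpoints[2][key])

    def test_tie_goes_to_earliest(self):
        res, key = self._result([(0.5, 0.5), (0.5, 0.5)])
        best = select_best_model(res)
        np.testing.assert_array_equal(best.state_dict()[key],
                                      res.checkpoints[0][key])


class TestTrainedDiagnostics:
    def test_reconstruction_rate_trend_increases(self, full_trainings):
        """Reconstruction rate climbs over training (positive Spearman
        rank correlation with epoch in most seeds)."""
        from scipy import stats

        wins = 0
        for res in full_trainings.values():
            rates = [r.reconstruction_rate for r in res.history]
            rho = stats.spearmanr(np.arange(len(rates)), rates).statistic
            if rho > 0:
                wins += 1
        assert wins >= 4

    def test_stabilization_improves_over_training(self, study_data, full_trainings):
        """After training, the prediction-discrepancy loss at a fresh
        adversarial perturbation is below its epoch-1 value (median seeds)."""
        from olbac.afse import adversarial_perturbation_batch, afse_loss
        from olbac.autodiff import Tensor
        from olbac.encoder import GraphBatch
        from olbac.model import OlbacModel

        graphs = [chem.parse_smiles(s) for s in study_data["df"].smiles[:80]]
        batch = GraphBatch.from_graphs(graphs)
        deltas = []
        for seed, res in full_trainings.items():
            losses = {}
            for tag, state in (("first", res.checkpoints[0]),
                               ("last", res.checkpoints[-1])):
                model = OlbacModel(res.model.config)
                model.load_state_dict(state)
                model.eval()
                f, _ = model.encoder(batch)
                d = adversarial_perturbation_batch(
                    f.data, model.predictor, 1.0, 0.01,
                    np.random.default_rng(seed))
                losses[tag] = float(afse_loss(Tensor(f.data), d,
                                              model.predictor).data)
            deltas.append(losses["last"] - losses["first"])
        assert np.median(deltas) < 0


class TestCheckpointing:
    def test_save_load_roundtrip(self, tmp_path, small_dataset):
        res = train(small_dataset, TrainConfig(epochs=1, seed=0), SMALL_MODEL)
        path = tmp_path / "model.npz"
        res.model.save(path)
        from olbac.model import OlbacModel
        loaded = OlbacModel.load(path)
        graphs = [chem.parse_smiles(s) for s in small_dataset.smiles[:5]]
        np.testing.assert_array_equal(predict(res.model, graphs),
                                      predict(loaded, graphs))
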
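import numpy as np
import pytest

import dissogp as dg
from dissogp.ann import (
    MLPConfig, MLPModel, Snapshot, TrainingDomainError, TrainingTrace,
    mlp_forward, mlp_train, select_best_snapshot,
)
from dissogp.metrics import rmse


def _model(weights, activation="tanh", layout=(2,)):
    cfg = MLPConfig(hidden_layout=layout, activation=activation, max_epochs=1)
    return MLPModel([(np.asarray(W, dtype=float), np.asarray(b, dtype=float))
                     for W, b in weights], cfg)


class TestForward:
    def test_zero_weights_tanh_outputs_zero(self):
        m = _model([(np.zeros((2, 3)), np.zeros(2)), (np.zeros((1, 2)), np.zeros(1))])
        assert mlp_forward(m, [1.0, -2.0, 0.5]) == 0.0

    def test_identity_linear_layer(self):
        m = _model([(np.array([[1.0, 0.0]]), np.zeros(1))],
                   activation="linear", layout=(1,))
        assert mlp_forward(m, [3.7, -1.0]) == pytest.approx(3.7)

    def test_hand_computed_2_2_1_tanh(self):
        W1 = np.array([[0.5, -0.3], [0.1, 0.8]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.2, -0.7]])
        b2 = np.array([0.05])
        m = _model([(W1, b1), (W2, b2)])
        x = np.array([0.4, -0.6])
        h = np.tanh(W1 @ x + b1)
        expected = np.tanh(W2 @ h + b2)[0]
        assert mlp_forward(m, x) == pytest.approx(expected, abs=1e-12)

    def test_arity_mismatch(self):
        m = _model([(np.zeros((2, 3)), np.zeros(2)), (np.zeros((1, 2)), np.zeros(1))])
        with pytest.raises(ValueError):
            mlp_forward(m, [1.0, 2.0])


class TestTraining:
    def test_learns_linear_map(self, rng):
        X = rng.uniform(-0.8, 0.8, (100, 1))
        y = X[:, 0]
        m, _ = mlp_train(X, y, MLPConfig(hidden_layout=(5,),
                                         max_epochs=50_000, seed=3))
        assert rmse(y, m.forward(X)) < 0.05

    def test_learns_xor(self):
        X = np.array([[-0.8, -0.8], [-0.8, 0.8], [0.8, -0.8], [0.8, 0.8]])
        y = np.array([-0.8, 0.8, 0.8, -0.8])
        m, _ = mlp_train(X, y, MLPConfig(hidden_layout=(4,),
                                         max_epochs=200_000, seed=1))
        assert np.all(np.sign(m.forward(X)) == np.sign(y))

    def test_snapshot_schedule(self, rng):
        X = rng.uniform(-0.5, 0.5, (30, 2))
        y = 0.5 * X[:, 0]
        _, trace = mlp_train(X, y, MLPConfig(hidden_layout=(3,),
                                             max_epochs=12_000, seed=0))
        assert [s.epoch for s in trace.snapshots] == [5_000, 10_000]

    def test_bit_reproducible(self, rng):
        X = rng.uniform(-0.5, 0.5, (30, 2))
        y = X[:, 0] * X[:, 1]
        runs = [mlp_train(X, y, MLPConfig(hidden_layout=(4,),
                                          max_epochs=3_000, seed=9))[0]
                for _ in range(2)]
        for (Wa, ba), (Wb, bb) in zip(runs[0].weights, runs[1].weights):
            assert np.array_equal(Wa, Wb) and np.array_equal(ba, bb)

    def test_jog_perturbs_and_resets_patience(self, rng):
        X = rng.uniform(-0.5, 0.5, (20, 1))
        y = 0.3 * X[:, 0]
        cfg = MLPConfig(hidden_layout=(2,), max_epochs=6_000,
                        patience_epochs=1_000, eval_interval=100, seed=2,
                        patience_tol=10.0)  # nothing can improve by 10 RMSE
        m, trace = mlp_train(X, y, cfg)
        assert trace.jog_epochs, "patience expiry must trigger jogs"
        assert np.diff([0] + trace.jog_epochs).min() >= cfg.patience_epochs

    def test_out_of_range_targets_rejected(self):
        X = np.zeros((4, 1))
        y = np.array([0.0, 50.0, 2.0, 1.0])  # raw % units, not scaled
        with pytest.raises(TrainingDomainError):
            mlp_train(X, y, MLPConfig(hidden_layout=(2,), activation="tanh"))

    def test_beats_null_predictor_on_study_data(self, noisy_ds):
        spec = dg.ScalingSpec.from_dataset(noisy_ds)
        scaled = dg.scale_linear(noisy_ds, spec)
        fold = dg.split_leave_one_formulation_out(scaled)[1]
        cfg = MLPConfig(hidden_layout=(8,), max_epochs=30_000, seed=4,
                        stop_points=(10_000, 20_000, 30_000))
        _, trace = dg.train_on_dataset(fold.train, cfg, test=fold.test)
        best = select_best_snapshot(trace, "test_rmse")
        X_test = fold.test.df[["d_mm", "t_min"]].to_numpy()
        y_test = fold.test.df["Q_pct"].to_numpy()
        y_train = fold.train.df["Q_pct"].to_numpy()
        net_rmse = rmse(y_test, best.forward(X_test))
        null_rmse = rmse(y_test, np.full_like(y_test, y_train.mean()))
        assert np.isfinite(net_rmse) and net_rmse < null_rmse


class TestSnapshotSelection:
    @staticmethod
    def _trace(test_rmses):
        cfg = MLPConfig(hidden_layout=(1,))
        snaps = [Snapshot(epoch=(i + 1) * 1000,
                          weights=[(np.full((1, 1), float(i)), np.zeros(1))],
                          train_rmse=1.0, test_rmse=r)
                 for i, r in enumerate(test_rmses)]
        return TrainingTrace(snapshots=snaps, config=cfg)

    def test_single_snapshot(self):
        m = select_best_snapshot(self._trace([0.5]), "test_rmse")
        assert m.epochs_trained == 1000

    def test_monotone_improvement_selects_last(self):
        m = select_best_snapshot(self._trace([0.5, 0.4, 0.3]), "test_rmse")
        assert m.epochs_trained == 3000

    def test_interior_minimum_selected(self):
        m = select_best_snapshot(self._trace([0.5, 0.2, 0.3, 0.25]), "test_rmse")
        assert m.epochs_trained == 2000

    def test_tie_prefers_earliest(self):
        m = select_best_snapshot(self._trace([0.4, 0.2, 0.2]), "test_rmse")
        assert m.epochs_trained == 2000

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            select_best_snapshot(TrainingTrace(config=MLPConfig(hidden_layout=(1,))))


def test_model_json_roundtrip(rng):
    X = rng.uniform(-0.5, 0.5, (10, 2))
    m, _ = mlp_train(X, 0.2 * X[:, 0], MLPConfig(hidden_layout=(3,),
                                                 max_epochs=500, seed=0))
    m2 = MLPModel.from_json(m.to_json())
    assert np.allclose(m.forward(X), m2.forward(X))
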
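"""Training protocol: class weights, stratified folds, early stopping,
metric arithmetic, summaries with t-tests, and the case drivers."""

import numpy as np
import pytest

from cnvsnn.nn.autograd import Tensor, bce_with_logits
from cnvsnn.train_eval import (
    FoldResult,
    TrainConfig,
    class_weights,
    cross_validate,
    evaluate,
    run_case,
    stratified_kfold,
    summarize,
    train_model,
)


class TestClassWeights:
    def test_worked_example(self):
        y = np.array([0] * 80 + [1] * 20)
        w = class_weights(y)
        assert w.w0 == pytest.approx(100 / 160)
        assert w.w1 == pytest.approx(100 / 40)

    def test_balanced_gives_unit_weights(self):
        w = class_weights(np.array([0, 1] * 25))
        assert w.w0 == w.w1 == 1.0

    def test_weighted_counts_invariant(self):
        y = np.array([0] * 80 + [1] * 20)
        w = class_weights(y)
        assert w.w0 * 80 == pytest.approx(w.n_total / 2)
        assert w.w1 * 20 == pytest.approx(w.n_total / 2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(10, dtype=int))


class TestStratifiedFolds:
    def test_exact_stratification_when_divisible(self):
        y = np.array([0] * 80 + [1] * 20)
        folds = stratified_kfold(y, k=10, seed=0)
        for _, te in folds:
            assert (y[te] == 0).sum() == 8
            assert (y[te] == 1).sum() == 2

    def test_partition_covers_everything_once(self):
        y = np.array([0] * 73 + [1] * 27)
        folds = stratified_kfold(y, k=10, seed=1)
        allte = np.concatenate([te for _, te in folds])
        assert sorted(allte.tolist()) == list(range(100))

    def test_seeded_reproducibility(self):
        y = np.array([0] * 50 + [1] * 50)
        a = stratified_kfold(y, k=5, seed=3)
        b = stratified_kfold(y, k=5, seed=3)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_small_class_rejected(self):
        y = np.array([0] * 95 + [1] * 5)
        with pytest.raises(ValueError, match="k=10"):
            stratified_kfold(y, k=10)


class _LinearToy:
    """Logistic regression on the autograd engine, for protocol tests."""

    name = "toy"

    def __init__(self, n_features: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w = Tensor(rng.normal(0, 0.1, size=(n_features, 1)), requires_grad=True)
        self.b = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        return [self.w, self.b]

    def _logits(self, X):
        return Tensor(np.asarray(X, float).reshape(len(X), -1)) @ self.w + self.b

    def predict(self, X):
        return (self._logits(X).data.reshape(-1) > 0).astype(int)

    def loss(self, X, y, sample_weight=None):
        return bce_with_logits(self._logits(X), y, sample_weight)


class TestTrainModel:
    def test_plateau_stops_after_patience(self):
        """Frozen gradients -> constant loss from epoch 1; patience 2 means
        epochs 2 and 3 fail to improve and training stops at epoch 3."""

        class Frozen(_LinearToy):
            def loss(self, X, y, sample_weight=None):
                return Tensor(np.array(1.0))  # constant, no parents

        m = Frozen(3)
        cfg = TrainConfig(max_epochs=100, patience=2, seed=0)
        _, hist = train_model(m, (np.zeros((10, 3)), np.array([0, 1] * 5)), cfg)
        assert hist["epochs"] == 3

    def test_seeded_history_reproducible(self):
        X = np.random.default_rng(0).normal(size=(24, 4))
        y = (X[:, 0] > 0).astype(int)
        h1 = train_model(_LinearToy(4, 1), (X, y), TrainConfig(max_epochs=5, patience=4, seed=2))[1]
        h2 = train_model(_LinearToy(4, 1), (X, y), TrainConfig(max_epochs=5, patience=4, seed=2))[1]
        assert h1["loss"] == h2["loss"]

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        m = _LinearToy(2)
        m, hist = train_model(m, (X, y), TrainConfig(max_epochs=300, patience=100, lr=0.05, seed=0))
        assert evaluate(m, (X, y)).acc == 1.0
        assert hist["loss"][-1] < hist["loss"][0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model(_LinearToy(2), (np.zeros((0, 2)), np.zeros(0)), TrainConfig())


class TestEvaluate:
    def test_metric_arithmetic_from_counts(self):
        r = FoldResult(fold=0, tp=197, fn=3, tn=793, fp=7)
        assert r.tpr == pytest.approx(0.985)
        assert r.tnr == pytest.approx(0.99125)
        assert r.acc == pytest.approx(0.99)
        assert r.f1 == pytest.approx(394 / 404)

    def test_degenerate_predictions(self):
        all_zero = FoldResult(fold=0, tp=0, fn=20, tn=80, fp=0)
        assert all_zero.acc == pytest.approx(0.8)
        assert all_zero.tpr == 0.0
        assert all_zero.tnr == 1.0
        assert all_zero.f1 == 0.0
        perfect = FoldResult(fold=0, tp=20, fn=0, tn=80, fp=0)
        assert perfect.acc == perfect.tpr == perfect.tnr == perfect.f1 == 1.0

    def test_counts_sum_to_test_size(self):
        class Majority:
            name = "maj"

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        X = np.zeros((30, 2))
        y = np.array([0] * 24 + [1] * 6)
        r = evaluate(Majority(), (X, y))
        assert r.n == 30
        assert r.tn == 24 and r.fn == 6


class TestSummarize:
    def _folds(self, values, name):
        return [
            FoldResult(fold=i, tp=int(v * 100), fn=int((1 - v) * 100), tn=100, fp=0, model=name)
            for i, v in enumerate(values)
        ]

    def test_identical_models_give_p_one(self):
        vals = [0.9, 0.8, 0.85]
        s = summarize({"a": self._folds(vals, "a"), "b": self._folds(vals, "b")}, "a")
        assert s.table.loc["b", "tpr_p"] == pytest.approx(1.0)

    def test_mean_and_sd(self):
        folds = self._folds([0.1, 0.2, 0.3], "a")
        accs = np.array([f.acc for f in folds])
        s = summarize({"a": folds, "b": folds}, "a")
        assert s.table.loc["a", "acc_mean"] == pytest.approx(accs.mean())
        assert s.table.loc["a", "acc_sd"] == pytest.approx(accs.std(ddof=1))

    def test_separated_samples_significant(self):
        a = self._folds([0.95, 0.96, 0.94, 0.95, 0.96], "a")
        b = self._folds([0.55, 0.56, 0.54, 0.55, 0.56], "b")
        s = summarize({"a": a, "b": b}, "a")
        assert s.table.loc["b", "acc_p"] < 0.001

    def test_zero_variance_guard(self):
        a = self._folds([0.9, 0.9], "a")
        b = self._folds([0.5, 0.5], "b")
        s = summarize({"a": a, "b": b}, "a")
        assert s.table.loc["b", "acc_p"] == 0.0


class TestCrossValidationProtocol:
    def _data(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] + 0.2 * rng.normal(size=60) > 0).astype(int)
        return X, y

    def test_cross_validate_runs_and_is_seeded(self):
        X, y = self._data()
        cfg = TrainConfig(max_epochs=20, patience=10, lr=0.05, seed=7)
        f = lambda shape, seed, train_X=None: _LinearToy(int(np.prod(shape)), seed)
        r1 = cross_validate(f, X, y, cfg, k=5)
        r2 = cross_validate(f, X, y, cfg, k=5)
        assert [(a.tp, a.fp, a.tn, a.fn) for a in r1] == [(a.tp, a.fp, a.tn, a.fn) for a in r2]
        assert sum(r.n for r in r1) == 60

    def test_run_case_spike_sweep_shape(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, size=(40, 2, 10))
        y = np.array([0, 1] * 20)
        cfg = TrainConfig(max_epochs=3, patience=2, seed=0)
        f = lambda shape, seed, train_X=None: _LinearToy(int(np.prod(shape)), seed)
        table = run_case("spike_sweep", (X, y), {"toy": f}, cfg, k=2, thresholds=(0.1, 0.5, 0.9))
        assert sorted(table["threshold"].unique()) == [0.1, 0.5, 0.9]
        assert len(table) == 3 * 2  # thresholds x folds

    def test_run_case_ablation_reduces_channels(self):
        rng = np.random.default_rng(7)
        labels = ("Fz", "Cz", "Pz", "C3", "C4", "O1")
        X = rng.uniform(0, 1, size=(40, 6, 8))
        y = np.array([0, 1] * 20)
        seen = {}

        def probe(shape, seed, train_X=None):
            seen["shape"] = shape
            return _LinearToy(int(np.prod(shape)), seed)

        run_case("ablation5", (X, y), {"toy": probe},
                 TrainConfig(max_epochs=2, patience=1, seed=0), k=2, channel_labels=labels)
        assert seen["shape"] == (5, 8)

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError, match="unknown case"):
            run_case("case4", (np.zeros((4, 1, 2)), np.array([0, 1, 0, 1])), {},
                     TrainConfig(max_epochs=2, patience=1))
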
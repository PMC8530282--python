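"""Training protocol, early stopping, CV, architecture search, linear baselines."""

import numpy as np
import pytest

from isomapnet.netlayers import LayerSpec, NetworkSpec, build_network
from isomapnet.preprocess import SplitAssignment
from isomapnet.training import (
    EarlyStopper,
    SearchResult,
    TrainingConfig,
    TrainingError,
    WIDTH_GRID,
    architecture_search,
    cross_validate,
    fit_elastic_net,
    fit_logistic,
    train,
)


def linear_toy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X[:, 0] + 2 * X[:, 1] > 0).astype(int)
    return X, y


class TestTrain:
    def test_separable_problem_reaches_full_training_accuracy(self):
        X, y = linear_toy()
        spec = NetworkSpec(input_dim=2, layers=[LayerSpec("dense", 8)],
                           dropout_rate=0.0)
        model = build_network(spec, seed=0)
        # a generous learning rate: this checks the optimizer machinery on an
        # easy problem, not the fixed study protocol
        cfg = TrainingConfig(seed=0, dropout=0.0, batch_size=32, learning_rate=0.05)
        model, log = train(model, (X, y), (X, y), cfg)
        acc = np.mean((model.predict_proba(X) >= 0.5) == y)
        assert acc == 1.0
        assert log.stopped_epoch <= 40

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        y = np.zeros(10, dtype=int)
        spec = NetworkSpec(input_dim=2, layers=[])
        model = build_network(spec, seed=0)
        with pytest.raises(TrainingError, match="single class"):
            train(model, (X, y), (X, y), TrainingConfig())

    def test_same_seed_reproduces_log(self):
        X, y = linear_toy(seed=1)
        spec = NetworkSpec(input_dim=2, layers=[LayerSpec("dense", 4)])
        cfg = TrainingConfig(seed=5, epochs=8)
        logs = []
        for _ in range(2):
            model = build_network(spec, seed=5)
            _, log = train(model, (X[:150], y[:150]), (X[150:], y[150:]), cfg)
            logs.append(log)
        assert logs[0].train_loss == logs[1].train_loss
        assert logs[0].val_accuracy == logs[1].val_accuracy
        assert logs[0].best_epoch == logs[1].best_epoch

    def test_returned_model_is_best_epoch_snapshot(self):
        # validation accuracy is recomputed from the returned parameters and
        # must equal the best recorded value
        X, y = linear_toy(seed=2)
        spec = NetworkSpec(input_dim=2, layers=[LayerSpec("dense", 4)])
        model = build_network(spec, seed=2)
        cfg = TrainingConfig(seed=2, epochs=15)
        model, log = train(model, (X[:150], y[:150]), (X[150:], y[150:]), cfg)
        val_acc = np.mean((model.predict_proba(X[150:]) >= 0.5) == y[150:])
        assert val_acc == pytest.approx(max(log.val_accuracy))
        assert log.val_accuracy[log.best_epoch - 1] == pytest.approx(max(log.val_accuracy))


class TestEarlyStopper:
    def test_flat_sequence_stops_patience_after_best(self):
        stopper = EarlyStopper(patience=10)
        seq = [0.6, 0.7] + [0.7] * 30  # ties never reset patience
        stopped_at = None
        for epoch, v in enumerate(seq, start=1):
            if stopper.update(epoch, v):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 2
        assert stopped_at == stopper.best_epoch + 10

    def test_strict_improvement_resets(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1, 0.5)
        assert not stopper.update(2, 0.4)
        assert not stopper.update(3, 0.6)  # new best resets
        assert not stopper.update(4, 0.6)
        assert stopper.update(5, 0.6)


class TestCrossValidate:
    def _folds(self, sample_ids, labels, n_folds=5):
        split = SplitAssignment()
        by_class = {0: [], 1: []}
        for s, l in zip(sample_ids, labels):
            split.split[s] = "train"
            by_class[l].append(s)
        i = 0
        for l in (0, 1):
            for s in by_class[l]:
                split.fold[s] = (i % n_folds) + 1
                i += 1
        return split

    def test_mean_is_average_of_folds(self):
        X, y = linear_toy(n=100, seed=3)
        ids = [f"s{i}" for i in range(100)]
        folds = self._folds(ids, y)
        spec = NetworkSpec(input_dim=2, layers=[LayerSpec("dense", 4)])
        cfg = TrainingConfig(seed=3, epochs=5)
        mean, per_fold = cross_validate(spec, folds, (X, y, ids), cfg)
        assert len(per_fold) == 5
        assert mean == pytest.approx(np.mean(per_fold))

    def test_reproducible(self):
        X, y = linear_toy(n=80, seed=4)
        ids = [f"s{i}" for i in range(80)]
        folds = self._folds(ids, y)
        spec = NetworkSpec(input_dim=2, layers=[LayerSpec("dense", 2)])
        cfg = TrainingConfig(seed=4, epochs=3)
        a = cross_validate(spec, folds, (X, y, ids), cfg)
        b = cross_validate(spec, folds, (X, y, ids), cfg)
        assert a == b


class TestArchitectureSearch:
    def test_peak_at_64_depth_one(self):
        def evaluator(stack):
            return 1.0 - abs(np.log2(stack[0]) - 6) / 10 - 0.5 * (len(stack) - 1)

        result = architecture_search(evaluator)
        assert result.widths == [64]

    def test_recovers_planted_deep_stack(self):
        target = (256, 128, 64)

        def evaluator(stack):
            score = sum(1.0 for a, b in zip(stack, target) if a == b)
            if len(stack) > len(target):
                score -= 5.0
            return score

        result = architecture_search(evaluator)
        assert result.widths == [256, 128, 64]

    def test_all_equal_scores_pick_smallest_width_depth_one(self):
        result = architecture_search(lambda stack: 0.5)
        assert result.widths == [2]

    def test_candidate_budget_and_decreasing_widths(self):
        calls = []

        def evaluator(stack):
            calls.append(stack)
            return float(len(stack))  # always improves with depth

        result = architecture_search(evaluator)
        layer1 = [c for c in calls if len(c) == 1]
        assert len(layer1) == 9  # 2..512
        for depth in range(2, 10):
            layer_d = [c for c in calls if len(c) == depth]
            assert len(layer_d) < len([c for c in calls if len(c) == depth - 1]) or not layer_d
        assert all(a > b for a, b in zip(result.widths, result.widths[1:]))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration_on_planted_chains(self, seed):
        # score = leading agreement with a planted decreasing chain minus a
        # depth penalty; the chain is the unique global optimum, so greedy
        # search must coincide with brute-force enumeration
        rng = np.random.default_rng(seed)
        grid = (2, 4, 8, 16, 32)
        depth = int(rng.integers(1, 4))
        target = tuple(sorted(rng.choice(grid, size=depth, replace=False), reverse=True))

        def evaluator(stack):
            matches = sum(1 for a, b in zip(stack, target) if a == b)
            return matches - 0.01 * len(stack)

        def enumerate_stacks(prefix=()):
            if prefix:
                yield prefix
            cap = prefix[-1] if prefix else np.inf
            for w in grid:
                if w < cap:
                    yield from enumerate_stacks(prefix + (w,))

        best = max(enumerate_stacks(), key=evaluator)
        result = architecture_search(evaluator, widths=grid)
        assert tuple(result.widths) == best == target


class TestLogistic:
    def test_null_model_asymptotics(self):
        rng = np.random.default_rng(6)
        n = 10_000
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < 0.3).astype(int)
        coef, intercept = fit_logistic(X, y)
        # null slope sd ~ 1/sqrt(n p (1-p)) ~ 0.022; allow ~3.5 sd
        assert np.all(np.abs(coef) < 0.08)
        p = y.mean()
        assert intercept == pytest.approx(np.log(p / (1 - p)), abs=0.05)

    def test_duplicated_feature_splits_ridge_coefficients(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(500, 1))
        y = (x[:, 0] + 0.5 * rng.normal(size=500) > 0).astype(int)
        X = np.hstack([x, x])
        coef, _ = fit_logistic(X, y, l2=0.01)
        assert coef[0] == pytest.approx(coef[1], rel=1e-4)

    def test_intercept_only_prediction_is_mean(self):
        y = np.array([0, 0, 1, 1, 1])
        X = np.zeros((5, 1))
        coef, intercept = fit_logistic(X, y)
        p = 1 / (1 + np.exp(-intercept))
        assert p == pytest.approx(0.6, abs=1e-6)


class TestElasticNet:
    def test_huge_l1_zeroes_all_slopes(self):
        X, y = linear_toy(n=100, seed=8)
        coef, _ = fit_elastic_net(X, y, l1=1e3, l2=0.0)
        assert np.all(coef == 0.0)

    def test_no_penalty_matches_logistic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 3))
        logit = X @ [0.5, -1.0, 0.2]
        y = (rng.random(300) < 1 / (1 + np.exp(-logit))).astype(int)
        c1, b1 = fit_elastic_net(X, y, l1=0.0, l2=0.0, tol=1e-13)
        c2, b2 = fit_logistic(X, y)
        assert np.allclose(c1, c2, atol=1e-6)
        assert b1 == pytest.approx(b2, abs=1e-6)

    def test_objective_not_worse_than_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)

        def objective(coef, intercept, l1, l2):
            z = X @ coef + intercept
            nll = np.mean(np.logaddexp(0, z) - y * z)
            return nll + l1 * np.abs(coef).sum() + l2 * (coef**2).sum()

        coef, b0 = fit_elastic_net(X, y, l1=0.01, l2=0.01)
        assert objective(coef, b0, 0.01, 0.01) <= objective(np.zeros(4), 0.0, 0.01, 0.01) + 1e-12

    def test_two_dimensional_grid_optimum(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 2))
        logit = X @ [1.0, -0.5]
        y = (rng.random(120) < 1 / (1 + np.exp(-logit))).astype(int)
        l1 = l2 = 0.05
        coef, b0 = fit_elastic_net(X, y, l1=l1, l2=l2)

        def objective(c0, c1, b):
            z = X[:, 0] * c0 + X[:, 1] * c1 + b
            return (np.mean(np.logaddexp(0, z) - y * z)
                    + l1 * (abs(c0) + abs(c1)) + l2 * (c0**2 + c1**2))

        ours = objective(coef[0], coef[1], b0)
        grid = np.linspace(-2, 2, 81)
        best = min(
            objective(c0, c1, b)
            for c0 in grid for c1 in grid for b in np.linspace(-1, 1, 21)
        )
        assert ours <= best + 1e-6
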
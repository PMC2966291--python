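import numpy as np
import pytest

from ngn.config import TrainingConfig
from ngn.errors import DesignError, TokenizationError
from ngn.experiments import (
    DESCRIPTOR_NAMES,
    baseline_ann_predict,
    baseline_ann_train,
    compare_methods,
    descriptor_vector,
    make_folds,
    run_trials,
)
from ngn.metrics import POS, NEG


class TestMakeFolds:
    def test_leave20_five_folds_fifty_trials(self):
        plan = make_folds(10, "leave20_cv", seed=0)
        assert len(plan.folds) == 5
        assert all(len(f) == 2 for f in plan.folds)
        assert plan.reps_per_fold == 10
        assert plan.n_trials == 50

    def test_leave5_twenty_singleton_folds(self):
        plan = make_folds(20, "leave5_cv", seed=0)
        assert len(plan.folds) == 20
        assert all(len(f) == 1 for f in plan.folds)
        assert plan.n_trials == 20

    def test_folds_partition_indices(self):
        for scheme, n in [("leave20_cv", 23), ("leave5_cv", 41), ("grouped5", 18)]:
            plan = make_folds(n, scheme, targets=np.arange(n), seed=3)
            all_idx = np.sort(np.concatenate(plan.folds))
            assert np.array_equal(all_idx, np.arange(n))
            sizes = [len(f) for f in plan.folds]
            assert max(sizes) - min(sizes) <= 1

    def test_grouped5_round_robin_deal(self):
        targets = np.arange(1, 11, dtype=float)
        plan = make_folds(10, "grouped5", targets=targets, seed=0)
        # cluster c holds sorted ranks c+1 and c+6
        for c, fold in enumerate(plan.folds):
            assert sorted(targets[fold]) == [c + 1, c + 6]

    def test_grouped5_clusters_span_output_range(self):
        rng = np.random.default_rng(0)
        targets = rng.random(50)
        plan = make_folds(50, "grouped5", targets=targets, seed=0)
        means = [targets[f].mean() for f in plan.folds]
        assert max(means) - min(means) < (targets.max() - targets.min()) / 5

    def test_random5_draws_fresh_fifth_per_trial(self):
        plan = make_folds(25, "random5", seed=1, n_trials=4)
        rng = np.random.default_rng(0)
        test1, train1 = plan.trial_split(0, rng)
        assert len(test1) == 5 and len(train1) == 20
        assert not set(test1) & set(train1)

    def test_designed_needs_explicit_split(self):
        with pytest.raises(DesignError):
            make_folds(10, "designed")
        plan = make_folds(10, "designed", test_indices=[7, 8, 9])
        assert plan.n_trials == 10  # one explicit split, ten repetitions

    def test_too_small_dataset(self):
        with pytest.raises(DesignError):
            make_folds(3, "leave20_cv")


class TestDescriptorVector:
    def test_simple_counts(self, extended):
        v = dict(zip(DESCRIPTOR_NAMES, descriptor_vector("CCO", extended)))
        assert v["n_C"] == 2 and v["n_O"] == 1
        assert v["n_branch"] == 0 and v["n_tokens"] == 3

    def test_isopentanol_counts(self, extended):
        v = dict(zip(DESCRIPTOR_NAMES, descriptor_vector("CC(C)CCO", extended)))
        assert v["n_branch"] == 1 and v["n_C"] == 5

    def test_bond_and_ring_counts(self, extended):
        v = dict(zip(DESCRIPTOR_NAMES, descriptor_vector("C1=CC=CC=C1", extended)))
        assert v["n_bond_="] == 3 and v["n_ring_digit"] == 2

    def test_empty_string_errors(self, extended):
        with pytest.raises(TokenizationError):
            descriptor_vector("", extended)


class TestBaselineANN:
    def test_one_exemplar_fit_converges(self):
        model = baseline_ann_train([[0.0, 1.0]], [0.7], seed=0, max_epochs=2000)
        assert model.converged
        assert abs(baseline_ann_predict(model, [0.0, 1.0]) - 0.7) < 0.1

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        X = rng.random((1, 3))
        t = np.array([0.6])
        model = baseline_ann_train(X, t, seed=2, max_epochs=0, max_restarts=0)
        # max_epochs=0 leaves the random initial weights untouched
        from ngn.experiments import _ann_forward

        x = (X[0] - model.x_lo) / model.x_span
        hid, out = _ann_forward(model, x)
        d_out = (t[0] - out) * out * (1 - out)
        d_hid = hid * (1 - hid) * (model.w2[0] * d_out)
        analytic = np.outer(d_hid, x)
        step = 1e-6
        for idx in np.ndindex(model.w1.shape):
            orig = model.w1[idx]
            model.w1[idx] = orig + step
            ep = 0.5 * (t[0] - _ann_forward(model, x)[1]) ** 2
            model.w1[idx] = orig - step
            em = 0.5 * (t[0] - _ann_forward(model, x)[1]) ** 2
            model.w1[idx] = orig
            numeric = -(ep - em) / (2 * step)
            assert analytic[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-10)

    def test_xor_learnable_with_two_hidden_units(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        t = np.array([0.2, 0.8, 0.8, 0.2])
        model = baseline_ann_train(X, t, seed=1, max_epochs=5000,
                                   rmse_threshold=0.05, max_restarts=4)
        assert model.converged
        assert model.final_rmse < 0.05


class TestStructureVersusCounts:
    def test_ngn_beats_count_descriptors_on_adjacency_task(self, subset):
        """When the label depends on token adjacency (substring 'C(C'),
        count descriptors cannot see where features occur but the
        grammar-structured network can; its held-out concordance should be
        higher.  Fixed-seed stochastic benchmark."""
        from ngn.metrics import classification_metrics, confusion_from_predictions
        from ngn.network import predict_many, train
        from ngn.synthetic import SynthTask, make_dataset

        task = SynthTask(kind="classification", label_rule="substring_presence",
                         param="C(C", n=100, max_depth=12, seed=13)
        data = make_dataset(task, subset)
        idx = np.arange(100)
        np.random.default_rng(1).shuffle(idx)
        tr, te = idx[:75], idx[75:]
        strings = [s for s, _ in data]
        labels = [y for _, y in data]
        targets = [0.8 if y == POS else 0.2 for y in labels]

        cfg = TrainingConfig(hidden_size=8, max_epochs=800, max_restarts=1, seed=0)
        lib, _ = train([(strings[i], targets[i]) for i in tr], subset, cfg, seed=3)
        preds_ngn = predict_many(lib, [strings[i] for i in te], subset)
        q_ngn = classification_metrics(
            confusion_from_predictions(preds_ngn, [labels[i] for i in te], 0.5)
        )["Q"]

        X = np.array([descriptor_vector(s, subset) for s in strings])
        ann = baseline_ann_train(X[tr], [targets[i] for i in tr], seed=3,
                                 max_epochs=800, max_restarts=1)
        preds_ann = [baseline_ann_predict(ann, X[i]) for i in te]
        q_ann = classification_metrics(
            confusion_from_predictions(preds_ann, [labels[i] for i in te], 0.5)
        )["Q"]
        assert q_ngn > q_ann


class FakeReport:
    def __init__(self, eps):
        import pandas as pd

        self.trials = pd.DataFrame({"epsilon": eps})


class TestCompareMethods:
    def test_identical_reports_no_winner(self):
        r = FakeReport([1.0, 2.0, 3.0])
        cmp = compare_methods(r, FakeReport([1.0, 2.0, 3.0]))
        assert cmp.winner == "none"

    def test_uniformly_smaller_epsilon_wins(self):
        a = FakeReport([1.0] * 8)
        b = FakeReport([2.0, 3.0, 2.5, 4.0, 2.2, 3.3, 2.8, 5.0])
        cmp = compare_methods(a, b)
        assert cmp.winner == "a"
        assert cmp.p == pytest.approx(1 / 256)

    def test_three_trials_lack_power(self):
        a = FakeReport([1.0, 1.0, 1.0])
        b = FakeReport([2.0, 3.0, 4.0])
        cmp = compare_methods(a, b)
        assert cmp.p >= 1 / 8
        assert cmp.winner == "none"


class TestRunTrials:
    def test_trial_record_count_and_determinism(self, subset):
        cfg = TrainingConfig(hidden_size=3, max_epochs=100, max_restarts=0, seed=0)
        data = [("CC", POS), ("CO", POS), ("CC(C)C", NEG), ("C", NEG),
                ("CCO", POS), ("CCC", NEG)]
        plan = make_folds(6, "designed", test_indices=[4, 5], reps_per_fold=2)
        rep1 = run_trials(data, subset, cfg, plan, task="classification")
        rep2 = run_trials(data, subset, cfg, plan, task="classification")
        assert rep1.n_trials == 2
        assert rep1.trials.equals(rep2.trials)

    def test_regression_report_carries_q2_and_epsilon(self, subset):
        cfg = TrainingConfig(hidden_size=3, max_epochs=150, max_restarts=0, seed=1)
        data = [("C", 0.2), ("CC", 0.35), ("CCC", 0.5), ("CCCC", 0.65),
                ("CCCCC", 0.8), ("CCO", 0.4)]
        plan = make_folds(6, "designed", test_indices=[2, 5], reps_per_fold=1)
        rep = run_trials(data, subset, cfg, plan, task="regression")
        assert {"q2", "epsilon", "epsilon_sd"} <= set(rep.trials.columns)
        assert rep.n_trials == 1

    def test_aggregates_cover_converged_trials_only(self, subset):
        cfg = TrainingConfig(hidden_size=2, max_epochs=2, max_restarts=0, seed=0)
        data = [("CC", POS), ("CO", NEG), ("C", POS), ("CCC", NEG)]
        plan = make_folds(4, "designed", test_indices=[3], reps_per_fold=3)
        rep = run_trials(data, subset, cfg, plan, task="classification")
        assert rep.n_converged <= rep.n_trials
        if rep.n_converged == 0:
            assert rep.aggregates == {}
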
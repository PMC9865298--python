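import numpy as np
import pytest

from posturekit import (
    AccelStream,
    ConfusionMatrix,
    ModelConfig,
    confusion,
    cross_validate,
    downsample,
    metrics,
)
from posturekit.errors import ConfigurationError, ValidationError
from posturekit.evaluation import make_cv_plan
from oracles import brute_force_binary_metrics


def binary_example():
    """20 samples with one-vs-rest counts TP=8, TN=9, FP=1, FN=2 for class A."""
    y_true = ["A"] * 10 + ["B"] * 10
    y_pred = ["A"] * 8 + ["B"] * 2 + ["A"] * 1 + ["B"] * 9
    return np.array(y_true), np.array(y_pred)


class TestConfusion:
    def test_identical_sequences_are_diagonal(self):
        y = np.array(["standing", "lying", "sitting", "lying"])
        cm = confusion(y, y)
        assert np.trace(cm.counts) == 4
        assert cm.counts.sum() - np.trace(cm.counts) == 0

    def test_hand_tallied_one_vs_rest_counts(self):
        y_true, y_pred = binary_example()
        cm = confusion(y_true, y_pred, labels=("A", "B"))
        assert cm.class_counts("A") == (8, 9, 1, 2)
        assert cm.class_counts("B") == (9, 8, 2, 1)
        assert cm.total == 20

    def test_empty_inputs_give_zero_matrix(self):
        cm = confusion(np.array([]), np.array([]), labels=("A", "B"))
        assert cm.counts.sum() == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion(np.array(["A"]), np.array(["A", "B"]))

    def test_per_class_counts_partition_total(self):
        y_true, y_pred = binary_example()
        cm = confusion(y_true, y_pred)
        for label in cm.labels:
            assert sum(cm.class_counts(label)) == cm.total


class TestMetrics:
    def test_hand_computed_binary_example(self):
        y_true, y_pred = binary_example()
        rep = metrics(confusion(y_true, y_pred, labels=("A", "B")))
        expected = brute_force_binary_metrics(8, 9, 1, 2)
        a = rep.per_class["A"]
        assert rep.accuracy == pytest.approx(0.85)
        assert a.accuracy == pytest.approx(expected["accuracy"])
        assert a.precision == pytest.approx(8 / 9)
        assert a.recall == pytest.approx(0.8)
        assert a.f1 == pytest.approx(16 / 19)

    def test_perfect_predictor_scores_one(self):
        y = np.array(["standing", "sitting", "bending", "lying"] * 5)
        rep = metrics(confusion(y, y))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1, 1, 1, 1)

    def test_all_wrong_balanced_binary_scores_zero(self):
        y_true = np.array(["A"] * 5 + ["B"] * 5)
        y_pred = np.array(["B"] * 5 + ["A"] * 5)
        rep = metrics(confusion(y_true, y_pred, labels=("A", "B")))
        assert rep.accuracy == 0.0
        assert rep.precision == 0.0
        assert rep.recall == 0.0
        assert rep.f1 == 0.0

    def test_macro_recall_equals_accuracy_on_balanced_set(self, rng):
        y_true = np.repeat(["standing", "sitting", "bending", "lying"], 25)
        y_pred = rng.choice(["standing", "sitting", "bending", "lying"], 100)
        rep = metrics(confusion(y_true, y_pred))
        assert rep.recall == pytest.approx(rep.accuracy, abs=1e-9)

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ("A", "B"))
        with pytest.raises(ValidationError):
            metrics(cm)


class TestCrossValidation:
    def separable(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat(["standing", "sitting", "bending", "lying"], n // 4)
        centers = {"standing": 0.0, "sitting": 2.0, "bending": 6.0, "lying": 9.0}
        X = np.array([centers[v] for v in y])[:, None] + rng.normal(0, 0.2, (n, 1))
        return X, y

    def test_folds_are_disjoint_and_exhaustive(self):
        _, y = self.separable(n=200)
        plan = make_cv_plan(y, folds=10, seed=0)
        assert np.array_equal(np.sort(np.unique(plan.fold_of)), np.arange(10))
        train_idx, val, test = plan.roles(3)
        assert len(set(train_idx) & set(test)) == 0
        assert len(set(val) & set(test)) == 0
        assert len(train_idx) + len(val) + len(test) == 200

    def test_eighty_ten_ten_split_sizes(self):
        _, y = self.separable(n=100)
        plan = make_cv_plan(y, folds=10, seed=0)
        for rep in range(10):
            train_idx, val, test = plan.roles(rep)
            assert (len(train_idx), len(val), len(test)) == (80, 10, 10)

    def test_separable_data_scores_high(self):
        X, y = self.separable(n=200)
        rep = cross_validate(X, y, ModelConfig.default("DT"), folds=10, seed=0)
        assert rep.accuracy > 0.95
        assert len(rep.fold_accuracies) == 10

    def test_constant_features_score_majority_prevalence(self):
        y = np.array(["standing"] * 120 + ["sitting"] * 80)
        X = np.ones((200, 2))
        rep = cross_validate(X, y, ModelConfig.default("DT"), folds=10, seed=0)
        assert rep.accuracy == pytest.approx(0.6, abs=0.1)

    def test_same_seed_identical_reports(self):
        X, y = self.separable(n=120, seed=3)
        a = cross_validate(X, y, ModelConfig.default("RF"), folds=10, seed=7)
        b = cross_validate(X, y, ModelConfig.default("RF"), folds=10, seed=7)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.accuracy == b.accuracy

    def test_class_smaller_than_fold_count_rejected(self):
        y = np.array(["A"] * 5 + ["B"] * 50)
        with pytest.raises(ConfigurationError, match="'A'"):
            make_cv_plan(y, folds=10)

    def test_grouped_folds_keep_groups_whole(self, mini_dataset):
        plan = make_cv_plan(
            mini_dataset.labels, folds=4, seed=0, groups=mini_dataset.groups
        )
        for g in np.unique(mini_dataset.groups):
            assert len(np.unique(plan.fold_of[mini_dataset.groups == g])) == 1


class TestDownsampling:
    def stream(self, f_hz=3.0, fs=50.0, n=1000):
        t = np.arange(n) / fs
        a = np.zeros((n, 3))
        a[:, 2] = np.sin(2 * np.pi * f_hz * t)
        labels = np.array(["standing"] * n, dtype=object)
        return AccelStream(t=t, a=a, fs=fs, labels=labels)

    def test_halving_keeps_every_second_sample(self):
        s = self.stream()
        d = downsample(s, 25.0)
        assert len(d) == 500
        assert d.fs == 25.0
        np.testing.assert_array_equal(d.a, s.a[::2])
        np.testing.assert_array_equal(d.t, s.t[::2])
        assert len(d.labels) == 500

    def test_constant_stream_values_unchanged(self):
        s = self.stream(f_hz=0.0)
        s = s.with_values(np.tile([0.1, 0.2, 0.3], (len(s), 1)))
        d = downsample(s, 25.0)
        np.testing.assert_array_equal(d.a, np.tile([0.1, 0.2, 0.3], (500, 1)))

    def test_low_frequency_amplitude_preserved(self):
        d = downsample(self.stream(f_hz=3.0), 25.0)
        amp = np.sqrt(2 * np.mean(d.a[:, 2] ** 2))
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            downsample(self.stream(), 30.0)
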
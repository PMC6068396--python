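"""Classifier grids, stratified folds, macro metrics, cross-validation."""

import numpy as np
import pytest

from vinehsi import (ModelConfig, PreprocessConfig, auc_macro, cross_validate,
                     enumerate_model_grid, f1_macro, fit_predict, hidden_size,
                     make_sample_table, n_ovo_subproblems, recall_macro,
                     stratified_folds)
from vinehsi.dataset_builder import SampleTable
from vinehsi.models import _per_class_auc


def _toy_table(features, labels, prefix="s"):
    features = np.asarray(features, dtype=float)
    n = len(labels)
    return SampleTable(
        features=features,
        variety=np.asarray(labels),
        day=np.zeros(n, dtype=int),
        sample_id=np.array([f"{prefix}{i}" for i in range(n)]),
        wavelengths=np.arange(features.shape[1], dtype=float) + 400,
    )


class TestHiddenSize:
    @pytest.mark.parametrize("code,expected", [("t", 280), ("a", 140), ("i", 250)])
    def test_study_scale_codes(self, code, expected):
        assert hidden_size(code, 250, 30) == expected

    def test_unknown_code_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            hidden_size("x", 250, 30)


class TestModelGrid:
    def test_svm_grid_size(self):
        assert len(enumerate_model_grid("svm")) == 18

    def test_mlp_grid_size(self):
        assert len(enumerate_model_grid("mlp")) == 18

    def test_svm_grid_contains_best_cell(self):
        assert ModelConfig("svm", svm_C=10.0, svm_kernel="linear") \
            in enumerate_model_grid("svm")

    def test_no_duplicates(self):
        for algo in ("svm", "mlp"):
            grid = enumerate_model_grid(algo)
            assert len(set(grid)) == len(grid)

    def test_config_field_exclusivity(self):
        with pytest.raises(ValueError):
            ModelConfig("svm", svm_C=1.0, svm_kernel="linear", mlp_hidden="t")
        with pytest.raises(ValueError):
            ModelConfig("mlp", mlp_hidden="t", mlp_activation="tanh")  # warm_start missing

    def test_polynomial_kernel_alias(self):
        assert ModelConfig("svm", svm_C=1.0, svm_kernel="polynomial").svm_kernel == "poly"


class TestStratifiedFolds:
    def test_study_scale_fold_counts(self):
        labels = np.repeat([f"V{i:02d}" for i in range(30)], 80)
        folds = stratified_folds(labels, k=5, seed=0)
        assert len(folds) == 5
        for split in folds:
            assert len(split.test_ids) == 480
            _, counts = np.unique(labels[split.test_ids], return_counts=True)
            assert np.all(counts == 16)

    def test_test_folds_partition_dataset(self):
        labels = np.repeat(["a", "b", "c"], 10)
        folds = stratified_folds(labels, k=5, seed=3)
        all_test = np.concatenate([f.test_ids for f in folds])
        assert len(all_test) == len(set(all_test)) == 30

    def test_same_seed_identical_splits(self):
        labels = np.repeat(["a", "b"], 20)
        a = stratified_folds(labels, k=5, seed=9)
        b = stratified_folds(labels, k=5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test_ids, fb.test_ids)

    def test_small_class_raises_naming_it(self):
        labels = np.array(["a"] * 10 + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            stratified_folds(labels, k=5, seed=0)


class TestFitPredict:
    def test_separable_clouds_linear_svm_perfect(self, rng):
        x_a = rng.normal(0.0, 0.1, size=(20, 4))
        x_b = rng.normal(5.0, 0.1, size=(20, 4))
        train = _toy_table(np.vstack([x_a[:15], x_b[:15]]), ["a"] * 15 + ["b"] * 15)
        test = _toy_table(np.vstack([x_a[15:], x_b[15:]]), ["a"] * 5 + ["b"] * 5, "t")
        config = ModelConfig("svm", svm_C=1.0, svm_kernel="linear")
        pred, proba, classes, _, _ = fit_predict(config, train, test, seed=0)
        assert recall_macro(test.variety, pred) == 1.0
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_one_vs_one_subproblem_counts(self, rng):
        assert n_ovo_subproblems(30) == 435
        # the fitted SVM really decomposes pairwise: 5 classes -> 10 subproblems
        labels = np.repeat(list("abcde"), 8)
        table = _toy_table(rng.normal(size=(40, 3)) + 3.0 * np.arange(40)[:, None] % 5,
                           labels)
        config = ModelConfig("svm", svm_C=1.0, svm_kernel="linear")
        _, _, _, est, _ = fit_predict(config, table, table, seed=0)
        est.decision_function_shape = "ovo"
        assert est.decision_function(table.features[:2]).shape[1] == 10

    def test_uninformative_features_give_chance_recall(self, rng):
        n_classes, per_class = 4, 40
        labels = np.repeat([f"c{i}" for i in range(n_classes)], per_class)
        features = np.ones((n_classes * per_class, 5)) + rng.normal(
            0, 1e-9, size=(n_classes * per_class, 5))
        idx = rng.permutation(len(labels))
        train, test = idx[:120], idx[120:]
        config = ModelConfig("svm", svm_C=1.0, svm_kernel="linear")
        pred, _, _, _, _ = fit_predict(config, _toy_table(features[train], labels[train]),
                                       _toy_table(features[test], labels[test], "t"), seed=0)
        recall = recall_macro(labels[test], pred)
        # chance = 1/4; binomial SE over 40 test samples, 3-sigma band
        se = np.sqrt(0.25 * 0.75 / len(test))
        assert abs(recall - 0.25) < 5 * se


class TestMacroMetrics:
    def test_recall_from_counts(self):
        truth = np.array(["a"] * 10)
        pred = np.array(["a"] * 9 + ["b"])
        assert recall_macro(truth, pred) == pytest.approx(0.9)

    def test_f1_from_precision_recall(self):
        # class 'a': precision 1 (1 predicted, correct), recall 0.5 -> F1 = 2/3
        truth = np.array(["a", "a"])
        pred = np.array(["a", "b"])
        per_class_f1 = 2 * 1.0 * 0.5 / (1.0 + 0.5)
        assert per_class_f1 == pytest.approx(2 / 3)

    def test_three_class_confusion_matrix_oracle(self):
        truth = np.array(list("aaaabbbbcccc"))
        pred = np.array(list("aabcbbbacccb"))
        classes = ["a", "b", "c"]
        recalls, f1s = [], []
        for c in classes:  # exhaustive per-class tally
            tp = np.sum((truth == c) & (pred == c))
            fn = np.sum((truth == c) & (pred != c))
            fp = np.sum((truth != c) & (pred == c))
            rec = tp / (tp + fn)
            prec = tp / (tp + fp) if tp + fp else 0.0
            recalls.append(rec)
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert recall_macro(truth, pred) == pytest.approx(np.mean(recalls))
        assert f1_macro(truth, pred) == pytest.approx(np.mean(f1s))

    def test_perfect_prediction_and_derangement(self):
        truth = np.repeat(["a", "b", "c"], 4)
        assert recall_macro(truth, truth) == 1.0
        derangement = {"a": "b", "b": "c", "c": "a"}
        pred = np.array([derangement[t] for t in truth])
        assert recall_macro(truth, pred) == 0.0

    def test_label_permutation_invariance(self, rng):
        truth = rng.choice(list("abc"), size=60)
        pred = rng.choice(list("abc"), size=60)
        mapping = {"a": "z", "b": "y", "c": "x"}
        truth2 = np.array([mapping[t] for t in truth])
        pred2 = np.array([mapping[p] for p in pred])
        assert recall_macro(truth, pred) == pytest.approx(recall_macro(truth2, pred2))
        assert f1_macro(truth, pred) == pytest.approx(f1_macro(truth2, pred2))

    def test_micro_equals_macro_on_balanced_truth(self, rng):
        truth = np.repeat(list("abcd"), 25)
        pred = rng.choice(list("abcd"), size=100)
        micro = np.mean(truth == pred)
        assert recall_macro(truth, pred) == pytest.approx(micro)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            recall_macro(np.array([]), np.array([]))


class TestAucMacro:
    def test_perfect_ranking(self):
        truth = np.array(["a", "a", "b", "b"])
        proba = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        assert auc_macro(truth, proba, np.array(["a", "b"])) == 1.0

    def test_anti_ranking(self):
        truth = np.array(["a", "a", "b", "b"])
        proba = np.array([[0.1, 0.9], [0.2, 0.8], [0.8, 0.2], [0.9, 0.1]])
        assert auc_macro(truth, proba, np.array(["a", "b"])) == 0.0

    def test_mann_whitney_oracle(self):
        truth = np.array(["p", "n", "p", "n", "p", "n"])
        scores = np.array([0.9, 0.45, 0.7, 0.3, 0.4, 0.2])
        proba = np.column_stack([1 - scores, scores])
        # U statistic: pairs (pos, neg) with score_pos > score_neg (ties = 1/2)
        pos = scores[truth == "p"]
        neg = scores[truth == "n"]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = u / (len(pos) * len(neg))
        got = _per_class_auc(truth, proba, np.array(["n", "p"]))["p"]
        assert got == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        truth = np.array(["p", "n", "p", "n", "p", "n"])
        scores = np.array([0.9, 0.45, 0.7, 0.3, 0.4, 0.2])
        proba = np.column_stack([1 - scores, scores])
        base = _per_class_auc(truth, proba, np.array(["n", "p"]))
        warped = np.column_stack([(1 - scores) ** 3, scores**3])
        trans = _per_class_auc(truth, warped, np.array(["n", "p"]))
        assert trans["p"] == pytest.approx(base["p"])
        assert trans["n"] == pytest.approx(base["n"])

    def test_unnormalized_rows_rejected(self):
        truth = np.array(["a", "b", "a"])
        proba = np.array([[0.9, 0.3], [0.2, 0.8], [0.7, 0.1]])
        with pytest.raises(ValueError, match="sum to 1"):
            auc_macro(truth, proba, np.array(["a", "b"]))


class TestCrossValidate:
    def test_high_separation_mlp_recall(self):
        table = make_sample_table(6, 1, 10, 40, separation=0.5, noise_sd=0.01, seed=4)
        config = ModelConfig("mlp", mlp_hidden="i", mlp_activation="tanh",
                             mlp_warm_start=False, mlp_max_iter=300)
        result = cross_validate(table, None, config, k=5, replicate_seed=1)
        assert result.recall >= 0.95

    def test_zero_separation_recall_is_chance(self):
        table = make_sample_table(5, 1, 20, 30, separation=0.0, noise_sd=0.01, seed=6)
        config = ModelConfig("svm", svm_C=1.0, svm_kernel="linear")
        result = cross_validate(table, None, config, k=5, replicate_seed=2)
        se = np.sqrt(0.2 * 0.8 / table.n_samples)
        assert abs(result.recall - 0.2) < 3 * se

    def test_same_seed_identical_result(self, small_table):
        config = ModelConfig("svm", svm_C=10.0, svm_kernel="linear")
        pp = PreprocessConfig(scatter=False, deriv_order=1, sg_window=5)
        a = cross_validate(small_table, pp, config, k=5, replicate_seed=5)
        b = cross_validate(small_table, pp, config, k=5, replicate_seed=5)
        assert (a.recall, a.f1, a.auc) == (b.recall, b.f1, b.auc)
        assert a.per_class == b.per_class

    def test_overall_is_macro_mean_of_per_class(self, small_table):
        config = ModelConfig("svm", svm_C=1.0, svm_kernel="rbf")
        result = cross_validate(small_table, None, config, k=5, replicate_seed=3)
        per_class_recall = np.mean([v["recall"] for v in result.per_class.values()])
        assert result.recall == pytest.approx(per_class_recall, abs=1e-12)

    def test_linear_svm_recall_nondecreasing_in_c(self):
        """Mirror of the C-parameter ordering: recall never degrades as C grows."""
        table = make_sample_table(5, 1, 12, 30, separation=0.15, noise_sd=0.05, seed=8)
        recalls = []
        for c in (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0):
            config = ModelConfig("svm", svm_C=c, svm_kernel="linear")
            recalls.append(cross_validate(table, None, config, k=5,
                                          replicate_seed=1).recall)
        assert all(b >= a - 0.02 for a, b in zip(recalls, recalls[1:]))
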
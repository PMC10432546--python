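"""Metrics, LOSO folds, model comparison, replicate and classifier checks."""

import numpy as np
import pytest
from scipy import stats

from atacsep.evaluation import (
    binarized_classification_metrics,
    classify_deconvoluted,
    compare_score_groups,
    loso_folds,
    mean_spearman,
    replicate_consistency_test,
    train_cell_classifier,
)


class TestLosoFolds:
    def test_one_fold_per_subject_no_leakage(self, small_training_set):
        folds = loso_folds(small_training_set)
        assert len(folds) == 3
        for train, test, subj in folds:
            assert set(test.subject) == {subj}
            assert subj not in set(train.subject)

    def test_test_sets_partition_all_pairs(self, small_training_set):
        folds = loso_folds(small_training_set)
        n_total = sum(len(test) for _, test, _ in folds)
        assert n_total == len(small_training_set)
        seen = []
        for _, test, _ in folds:
            seen.extend(test.bulk.sum(axis=1).tolist())
        # every pair appears exactly once across the test sides
        all_sums = sorted(small_training_set.bulk.sum(axis=1).tolist())
        assert sorted(seen) == pytest.approx(all_sums)

    def test_single_subject_rejected(self, small_training_set):
        only = small_training_set.subset(
            np.flatnonzero(small_training_set.subject == "S01")
        )
        with pytest.raises(ValueError, match="2 subjects"):
            loso_folds(only)


class TestMeanSpearman:
    def test_perfect_and_antitone(self):
        rng = np.random.default_rng(0)
        truth = rng.random((4, 2, 30))
        assert mean_spearman(truth, truth)["overall"] == pytest.approx(1.0)
        assert mean_spearman(-truth + 3.0, truth)["overall"] == pytest.approx(-1.0)

    def test_agrees_with_scipy_spearman_per_pair(self):
        """The vectorized rank/Pearson implementation matches scipy's
        spearmanr pair by pair (including tied values)."""
        rng = np.random.default_rng(1)
        pred = np.round(rng.random((6, 3, 50)), 1)  # induce ties
        truth = np.round(rng.random((6, 3, 50)), 1)
        got = mean_spearman(pred, truth)
        want = np.zeros(3)
        for i in range(3):
            rs = [
                stats.spearmanr(pred[n, i], truth[n, i]).statistic
                for n in range(6)
            ]
            want[i] = np.mean(rs)
        assert np.max(np.abs(got["per_type"] - want)) < 1e-12

    def test_degenerate_pairs_skipped_and_counted(self):
        pred = np.random.default_rng(2).random((3, 1, 10))
        truth = pred.copy()
        truth[0, 0] = 0.5  # constant -> undefined correlation
        out = mean_spearman(pred, truth)
        assert out["n_skipped"] == 1
        assert out["overall"] == pytest.approx(1.0)

    def test_too_few_masked_ocrs_rejected(self):
        pred = np.zeros((2, 1, 10))
        mask = np.zeros((1, 10), dtype=bool)
        mask[0, :2] = True
        with pytest.raises(ValueError, match="fewer than 3"):
            mean_spearman(pred, pred, mask)


class TestBinarizedMetrics:
    def test_perfect_scores(self):
        rng = np.random.default_rng(3)
        truth = (rng.random((5, 2, 40)) > 0.5).astype(float)
        out = binarized_classification_metrics(truth, truth)
        assert out["auroc"] == pytest.approx(1.0)
        assert out["auprc"] == pytest.approx(1.0)

    def test_random_scores_near_half_auroc(self):
        rng = np.random.default_rng(4)
        truth = (rng.random((30, 1, 400)) > 0.5).astype(float)
        pred = rng.random((30, 1, 400))
        out = binarized_classification_metrics(pred, truth)
        assert out["auroc"] == pytest.approx(0.5, abs=0.05)

    def test_auroc_equals_mann_whitney_identity(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(5):
            y = (rng.random(80) > 0.4).astype(int)
            s = rng.random(80)
            n1, n0 = y.sum(), (1 - y).sum()
            u = stats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided")
            assert abs(roc_auc_score(y, s) - u.statistic / (n1 * n0)) < 1e-12

    def test_all_single_class_rejected(self):
        truth = np.ones((3, 1, 10))
        with pytest.raises(ValueError, match="single-class"):
            binarized_classification_metrics(truth, truth)


class TestCompareScoreGroups:
    def test_identical_groups_corrected_p_is_one(self):
        x = np.linspace(0.5, 0.9, 13)
        out = compare_score_groups({"a": x, "b": x.copy()})
        assert out["p_bonferroni"].iloc[0] == pytest.approx(1.0)

    def test_all_positive_differences_give_exact_minimal_p(self):
        # n=13 strictly positive differences: the two-sided signed-rank p
        # is 2 / 2^13
        rng = np.random.default_rng(6)
        b = rng.random(13)
        out = compare_score_groups({"a": b + 10, "b": b})
        assert out["p_value"].iloc[0] == pytest.approx(2 / 2**13, rel=1e-9)

    def test_three_identical_groups_kruskal_p_one(self):
        x = np.linspace(0, 1, 8)
        out = compare_score_groups({"a": x, "b": x.copy(), "c": x.copy()})
        kw = out[out["test"] == "kruskal_wallis"]
        assert kw["p_value"].iloc[0] == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            compare_score_groups({"a": np.ones(5), "b": np.ones(6)})


class TestReplicateConsistency:
    @staticmethod
    def _fixture(within_sd=0.01, between_sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n_pairs, S, P = 6, 2, 80
        base = rng.normal(0, between_sd, size=(n_pairs, S, P))
        sources = np.empty((2 * n_pairs, S, P))
        for k in range(n_pairs):
            sources[2 * k] = base[k] + rng.normal(0, within_sd, size=(S, P))
            sources[2 * k + 1] = base[k] + rng.normal(0, within_sd, size=(S, P))
        pairs = [(2 * k, 2 * k + 1) for k in range(n_pairs)]
        strata = {"region": np.array(["R1"] * (2 * n_pairs))}
        return np.abs(sources), pairs, strata

    def test_exact_copies_correlate_perfectly(self):
        sources, pairs, strata = self._fixture(within_sd=0.0)
        out = replicate_consistency_test(sources, pairs, strata, n_random=5, seed=1)
        assert np.allclose(out[0].true_pair_correlations, 1.0)

    def test_true_pairs_beat_random_partners(self):
        sources, pairs, strata = self._fixture()
        out = replicate_consistency_test(sources, pairs, strata, n_random=20, seed=2)
        r = out[0]
        assert r.true_pair_correlations.mean() > r.random_pair_correlations.mean()
        assert r.p_value < 0.05

    def test_empty_null_rejected(self):
        sources, pairs, strata = self._fixture()
        with pytest.raises(ValueError, match="empty null"):
            replicate_consistency_test(sources, pairs, strata, n_random=0)


class TestCellClassifier:
    @staticmethod
    def _profiles(n_per_class=30, S=3, P=60, separated=True, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for i in range(S):
            base = np.zeros(P)
            if separated:
                base[i * (P // S) : (i + 1) * (P // S)] = 10.0
            X.append(rng.poisson(base + 0.2, size=(n_per_class, P)))
            y.extend([f"C{i}"] * n_per_class)
        return np.concatenate(X).astype(float), np.array(y)

    def test_separable_classes_reach_perfect_auroc(self):
        X, y = self._profiles()
        _, report = train_cell_classifier(X, y, cv_folds=3)
        assert report.auroc == pytest.approx(1.0, abs=1e-6)

    def test_default_hyperparameters(self):
        import inspect

        sig = inspect.signature(train_cell_classifier)
        assert sig.parameters["learning_rate"].default == 0.1
        assert sig.parameters["max_depth"].default == 10
        assert sig.parameters["n_estimators"].default == 100

    def test_label_permutation_destroys_signal(self):
        X, y = self._profiles(n_per_class=40)
        rng = np.random.default_rng(1)
        _, report = train_cell_classifier(X, rng.permutation(y), cv_folds=3)
        assert report.auroc == pytest.approx(0.5, abs=0.1)

    def test_confusion_rows_sum_to_class_counts(self):
        X, y = self._profiles(n_per_class=25)
        _, report = train_cell_classifier(X, y, cv_folds=5)
        assert report.confusion.sum(axis=1).tolist() == [25, 25, 25]

    def test_classify_ground_truth_sources_near_diagonal(self):
        X, y = self._profiles(n_per_class=40)
        clf, _ = train_cell_classifier(X, y, cv_folds=3)
        # arrange held-out-style source tensors: n samples x S x P rows in
        # the class order the classifier was trained on
        S, P = 3, X.shape[1]
        sources = X.reshape(S, 40, P).transpose(1, 0, 2)[:20]
        report = classify_deconvoluted(clf, sources, ("C0", "C1", "C2"))
        acc = np.trace(report.confusion) / report.confusion.sum()
        assert acc > 0.95
        assert report.confusion.sum(axis=1).tolist() == [20, 20, 20]

    def test_shuffled_rows_score_at_chance(self):
        X, y = self._profiles(n_per_class=40, seed=3)
        clf, _ = train_cell_classifier(X, y, cv_folds=3)
        rng = np.random.default_rng(4)
        S, P = 3, X.shape[1]
        shuffled = rng.permutation(X).reshape(-1, S, P)[:20]
        report = classify_deconvoluted(clf, shuffled, ("C0", "C1", "C2"))
        acc = np.trace(report.confusion) / report.confusion.sum()
        assert acc == pytest.approx(1 / S, abs=0.15)
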
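"""Stratified folds, metric family, ROC-AUC, McNemar, CV experiment."""

import itertools

import numpy as np
import pytest
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from audiotype.core import CLINICAL_LABELS, AudiogramSet, HearingLossLabel as L
from audiotype.evaluation import (
    ConfusionMatrix,
    aggregate_cv,
    binary_auc,
    confusion,
    mcnemar,
    metrics_from_confusion,
    roc_auc_micro_ovr,
    run_cv_experiment,
    stratified_folds,
)
from audiotype.models import ModelConfig, TreeConfig
from audiotype.synth import GeneratorConfig, generate_dataset


class TestStratifiedFolds:
    def test_balanced_forty_samples(self):
        labels = [c for c in CLINICAL_LABELS for _ in range(10)]
        folds = stratified_folds(labels, k=10, seed=0)
        for fold in folds.folds:
            assert len(fold) == 4
            assert sorted(labels[i].value for i in fold) == sorted(
                c.value for c in CLINICAL_LABELS)

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        labels = [CLINICAL_LABELS[i] for i in rng.integers(0, 4, 500)]
        folds = stratified_folds(labels, k=7, seed=3)
        all_idx = sorted(i for fold in folds.folds for i in fold)
        assert all_idx == list(range(500))

    def test_clinical_population_conductive_per_fold(self):
        # 657 conductive ears split over 10 folds -> 65 or 66 per fold
        labels = ([L.NORMAL] * 2584 + [L.CONDUCTIVE] * 657
                  + [L.MIXED] * 4028 + [L.SENSORINEURAL] * 7777)
        folds = stratified_folds(labels, k=10, seed=5)
        for fold in folds.folds:
            n_cond = sum(1 for i in fold if labels[i] is L.CONDUCTIVE)
            assert n_cond in (65, 66)

    def test_per_class_counts_differ_by_at_most_one(self):
        rng = np.random.default_rng(9)
        labels = [CLINICAL_LABELS[i] for i in rng.integers(0, 4, 333)]
        folds = stratified_folds(labels, k=5, seed=0)
        for c in CLINICAL_LABELS:
            counts = [sum(1 for i in fold if labels[i] is c) for fold in folds.folds]
            assert max(counts) - min(counts) <= 1

    def test_small_class_is_error(self):
        labels = [L.NORMAL] * 20 + [L.CONDUCTIVE] * 3
        with pytest.raises(ValueError, match="conductive"):
            stratified_folds(labels, k=5, seed=0)

    def test_split_train_test_disjoint(self):
        labels = [CLINICAL_LABELS[i % 4] for i in range(40)]
        folds = stratified_folds(labels, k=4, seed=2)
        for train, test in folds.split():
            assert set(train).isdisjoint(test)
            assert len(train) + len(test) == 40


class TestConfusion:
    def test_all_correct_diagonal(self):
        labels = [c for c in CLINICAL_LABELS for _ in range(3)]
        cm = confusion(labels, labels)
        assert np.array_equal(cm.counts, np.eye(4, dtype=int) * 3)

    def test_single_misclassification_location(self):
        cm = confusion([L.MIXED], [L.SENSORINEURAL])
        expected = np.zeros((4, 4), dtype=int)
        expected[2, 3] = 1  # row = true mixed, col = predicted sensorineural
        assert np.array_equal(cm.counts, expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        truth = [CLINICAL_LABELS[i] for i in rng.integers(0, 4, 60)]
        preds = [CLINICAL_LABELS[i] for i in rng.integers(0, 4, 60)]
        cm1 = confusion(truth, preds)
        perm = rng.permutation(60)
        cm2 = confusion([truth[i] for i in perm], [preds[i] for i in perm])
        assert np.array_equal(cm1.counts, cm2.counts)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([L.NORMAL], [])


class TestMetrics:
    def test_recall_sixty_nine_of_seventy(self):
        # conductive: 69 correct of 70 -> recall 98.57%
        counts = np.zeros((4, 4), dtype=int)
        counts[1, 1] = 69
        counts[1, 3] = 1
        counts[0, 0] = counts[2, 2] = counts[3, 3] = 100
        report = metrics_from_confusion(ConfusionMatrix(counts))
        m = report.per_class[L.CONDUCTIVE]
        assert m.tp == 69 and m.fn == 1
        assert round(100 * m.recall, 2) == 98.57

    def test_perfect_matrix_all_ones(self):
        cm = ConfusionMatrix(np.diag([10, 5, 8, 20]))
        report = metrics_from_confusion(cm)
        assert report.accuracy == report.precision == report.recall == report.f1 == 1.0
        for m in report.per_class.values():
            assert m.precision == m.recall == m.f1 == 1.0

    def test_metric_identities_on_random_matrices(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            counts = rng.integers(0, 40, (4, 4))
            counts[np.diag_indices(4)] += 5
            cm = ConfusionMatrix(counts)
            report = metrics_from_confusion(cm)
            total = counts.sum()
            # overall accuracy equals support-weighted recall
            assert report.accuracy == pytest.approx(report.recall)
            for i, c in enumerate(CLINICAL_LABELS):
                m = report.per_class[c]
                assert m.tp + m.fn == counts[i, :].sum()
                assert m.tp + m.fp == counts[:, i].sum()
                assert m.tp + m.tn + m.fp + m.fn == total

    def test_f1_zero_convention(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 5  # normal always predicted conductive
        counts[2, 2] = counts[3, 3] = 5
        counts[1, 1] = 5
        report = metrics_from_confusion(ConfusionMatrix(counts))
        assert report.per_class[L.NORMAL].f1 == 0.0

    def test_macro_vs_weighted(self):
        counts = np.array([[8, 2, 0, 0], [0, 1, 0, 0],
                           [0, 0, 5, 0], [0, 0, 0, 4]])
        rw = metrics_from_confusion(ConfusionMatrix(counts), "weighted")
        rm = metrics_from_confusion(ConfusionMatrix(counts), "macro")
        assert rw.recall != rm.recall

    def test_empty_matrix_error(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(np.zeros((4, 4), dtype=int)))


class TestAggregateCv:
    def test_identical_folds_sd_zero(self):
        cm = ConfusionMatrix(np.diag([5, 5, 5, 5]))
        reports = [metrics_from_confusion(cm)] * 3
        agg = aggregate_cv(reports)
        assert agg.mean["accuracy"] == 1.0 and agg.sd["accuracy"] == 0.0

    def test_mean_within_min_max(self):
        cms = [ConfusionMatrix(np.diag([5, 5, 5, 5])),
               ConfusionMatrix(np.array([[4, 1, 0, 0], [0, 5, 0, 0],
                                         [0, 0, 5, 0], [0, 0, 0, 5]]))]
        reports = [metrics_from_confusion(c) for c in cms]
        agg = aggregate_cv(reports)
        accs = [r.accuracy for r in reports]
        assert min(accs) <= agg.mean["accuracy"] <= max(accs)

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            aggregate_cv([metrics_from_confusion(ConfusionMatrix(np.diag([1, 1, 1, 1])))])


def _brute_force_auc(indicator, scores):
    wins = 0.0
    pairs = 0
    for (i_pos, s_pos), (i_neg, s_neg) in itertools.product(
            [(i, s) for i, s in zip(indicator, scores) if i],
            [(i, s) for i, s in zip(indicator, scores) if not i]):
        pairs += 1
        if s_pos > s_neg:
            wins += 1
        elif s_pos == s_neg:
            wins += 0.5
    return wins / pairs


class TestAuc:
    def test_binary_toy_three_quarters(self):
        ind = [1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.1]
        assert binary_auc(ind, scores) == pytest.approx(0.75)
        assert _brute_force_auc(ind, scores) == pytest.approx(0.75)

    def test_perfect_classifier_auc_one(self):
        truth = [c for c in CLINICAL_LABELS for _ in range(5)]
        proba = np.zeros((20, 4))
        for i, lab in enumerate(truth):
            proba[i, CLINICAL_LABELS.index(lab)] = 1.0
        assert roc_auc_micro_ovr(truth, proba) == 1.0

    def test_constant_scores_half(self):
        truth = [L.NORMAL, L.MIXED, L.CONDUCTIVE, L.SENSORINEURAL]
        proba = np.full((4, 4), 0.25)
        assert roc_auc_micro_ovr(truth, proba) == pytest.approx(0.5)

    def test_rank_statistic_equals_pair_counting(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            n = 40
            truth = [CLINICAL_LABELS[i] for i in rng.integers(0, 4, n)]
            raw = rng.random((n, 4))
            proba = raw / raw.sum(axis=1, keepdims=True)
            proba = np.round(proba, 2)  # induce ties
            got = roc_auc_micro_ovr(truth, proba)
            indicator = np.zeros((n, 4), dtype=bool)
            for i, lab in enumerate(truth):
                indicator[i, CLINICAL_LABELS.index(lab)] = True
            assert got == pytest.approx(
                _brute_force_auc(indicator.ravel(), proba.ravel()))

    def test_cross_check_against_sklearn_micro(self):
        rng = np.random.default_rng(22)
        n = 100
        truth_idx = rng.integers(0, 4, n)
        raw = rng.random((n, 4))
        proba = raw / raw.sum(axis=1, keepdims=True)
        truth = [CLINICAL_LABELS[i] for i in truth_idx]
        onehot = np.eye(4)[truth_idx]
        expected = roc_auc_score(onehot, proba, average="micro")
        assert roc_auc_micro_ovr(truth, proba) == pytest.approx(expected)

    def test_single_class_truth_error(self):
        with pytest.raises(ValueError):
            roc_auc_micro_ovr([L.NORMAL, L.NORMAL], np.full((2, 4), 0.25))


def _preds_with_pattern(truth, n_wrong_a, n_wrong_b, n_wrong_both=0):
    """Prediction pairs realising given discordant/concordant error counts."""
    def flip(lab):
        return L.MIXED if lab is L.NORMAL else L.NORMAL
    preds_a = list(truth)
    preds_b = list(truth)
    i = 0
    for _ in range(n_wrong_both):
        preds_a[i] = flip(truth[i]); preds_b[i] = flip(truth[i]); i += 1
    for _ in range(n_wrong_a):
        preds_a[i] = flip(truth[i]); i += 1
    for _ in range(n_wrong_b):
        preds_b[i] = flip(truth[i]); i += 1
    return preds_a, preds_b


class TestMcNemar:
    def test_twelve_two_with_correction(self):
        truth = [CLINICAL_LABELS[i % 4] for i in range(100)]
        preds_a, preds_b = _preds_with_pattern(truth, 12, 2)
        res = mcnemar(truth, preds_a, preds_b)
        assert (res.n01, res.n10) == (12, 2)
        assert res.statistic == pytest.approx(81 / 14)
        assert res.p_value == pytest.approx(0.0162, abs=2e-4)

    def test_twelve_two_without_correction(self):
        truth = [CLINICAL_LABELS[i % 4] for i in range(100)]
        preds_a, preds_b = _preds_with_pattern(truth, 12, 2)
        res = mcnemar(truth, preds_a, preds_b, continuity_correction=False)
        assert res.statistic == pytest.approx(100 / 14)

    def test_balanced_discordance(self):
        truth = [CLINICAL_LABELS[i % 4] for i in range(100)]
        preds_a, preds_b = _preds_with_pattern(truth, 10, 10)
        res = mcnemar(truth, preds_a, preds_b)
        assert res.statistic == pytest.approx(0.05)
        assert res.p_value == pytest.approx(0.823, abs=5e-4)

    def test_identical_classifiers_flagged(self):
        truth = [CLINICAL_LABELS[i % 4] for i in range(20)]
        preds_a, preds_b = _preds_with_pattern(truth, 0, 0, n_wrong_both=3)
        res = mcnemar(truth, preds_a, preds_b)
        assert res.no_discordant_pairs
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.n00 == 3 and res.n11 == 17

    def test_counts_conserve_sample_size(self):
        truth = [CLINICAL_LABELS[i % 4] for i in range(60)]
        preds_a, preds_b = _preds_with_pattern(truth, 5, 3, n_wrong_both=4)
        res = mcnemar(truth, preds_a, preds_b)
        assert res.n00 + res.n01 + res.n10 + res.n11 == 60

    def test_cross_check_against_statsmodels(self):
        truth = [CLINICAL_LABELS[i % 4] for i in range(200)]
        for n01, n10 in [(12, 2), (7, 7), (20, 5)]:
            preds_a, preds_b = _preds_with_pattern(truth, n01, n10)
            res = mcnemar(truth, preds_a, preds_b)
            table = [[res.n11, res.n10], [res.n01, res.n00]]
            sm = sm_mcnemar(table, exact=False, correction=True)
            assert res.statistic == pytest.approx(sm.statistic)
            assert res.p_value == pytest.approx(sm.pvalue)

    def test_agrees_with_exact_binomial_at_small_counts(self):
        # with few discordant pairs the chi-square approximation with
        # continuity correction is conservative relative to the exact
        # two-sided binomial test
        truth = [CLINICAL_LABELS[i % 4] for i in range(80)]
        for n01, n10 in [(8, 2), (10, 4), (12, 6), (6, 1)]:
            preds_a, preds_b = _preds_with_pattern(truth, n01, n10)
            res = mcnemar(truth, preds_a, preds_b)
            exact = binomtest(n01, n01 + n10, 0.5).pvalue
            assert res.p_value >= exact - 0.02
            # both agree on strong significance calls at alpha = 0.25
            assert (res.p_value < 0.25) == (exact < 0.25) or \
                abs(res.p_value - exact) < 0.1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar([L.NORMAL], [L.NORMAL], [])


@pytest.fixture(scope="module")
def dataset():
    return generate_dataset(GeneratorConfig(n=400, seed=77))


class TestRunCvExperiment:

    def test_tree_cv_structure(self, dataset):
        result = run_cv_experiment(dataset, TreeConfig(), k=5, seed=1)
        assert len(result.cv_report.fold_reports) == 5
        assert result.pooled_confusion.total == 400
        assert 0.5 < result.auc <= 1.0
        assert sorted(result.order.tolist()) == list(range(400))

    def test_reproducible_from_seed(self, dataset):
        r1 = run_cv_experiment(dataset, TreeConfig(), k=5, seed=1)
        r2 = run_cv_experiment(dataset, TreeConfig(), k=5, seed=1)
        assert r1.cv_report.mean == r2.cv_report.mean
        assert np.array_equal(r1.pooled_confusion.counts, r2.pooled_confusion.counts)

    def test_normalization_comparison_grid(self, dataset):
        # the four scaling methods all run through the same harness
        cfg = ModelConfig(architecture="lstm", units1=8, units2=6,
                          max_epochs=3, val_fraction=0.0, seed=0)
        grid = {}
        for method in ("zscore", "minmax", "robust", "maxabs"):
            result = run_cv_experiment(dataset, cfg, normalization=method,
                                       k=2, seed=3)
            grid[method] = result.cv_report.mean["accuracy"]
        assert set(grid) == {"zscore", "minmax", "robust", "maxabs"}
        assert all(0.0 <= v <= 1.0 for v in grid.values())

    def test_unlabelled_data_error(self, dataset):
        with pytest.raises(ValueError):
            run_cv_experiment(AudiogramSet(dataset.records), TreeConfig(), k=2, seed=0)
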
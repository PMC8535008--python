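"""Metrics against brute-force oracles, threshold policies, LOPOCV harness."""

import numpy as np
import pytest

from hsicad import evaluation, synthetic
from hsicad.evaluation import (
    ConfusionCounts,
    ExperimentSetting,
    UndefinedMetricError,
    aggregate_mean_sd,
    confusion_at_threshold,
    cross_dataset_eval,
    default_threshold_grid,
    dice,
    lopocv,
    mcc,
    paired_t_test,
    roc_auc,
    tune_threshold_patient_generic,
    tune_threshold_patient_specific,
)
from hsicad.models import ScoreMap


def brute_force_auc(scores, labels):
    """Pairwise concordance oracle for ROC-AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.1], [1, 0], 1.0),
            ([0.1, 0.9], [1, 0], 0.0),
            ([0.5, 0.5, 0.8, 0.2], [1, 0, 1, 0], 0.875),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties
            scores = rng.integers(0, 6, n) / 5.0
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        scores = rng.random(200)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(3 * scores), labels), abs=1e-12
        )

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])


def _map_from(scores, valid=None):
    scores = np.asarray(scores, float).reshape(1, -1)
    valid = np.ones_like(scores, bool) if valid is None else np.asarray(valid).reshape(1, -1)
    return ScoreMap(scores=scores, valid=valid)


class TestConfusion:
    def test_threshold_zero_all_positive(self):
        m = _map_from([0.2, 0.6, 0.9])
        c = confusion_at_threshold(m, np.array([[0, 1, 1]]), 0.0)
        assert (c.tn, c.fn) == (0, 0) and c.tp == 2 and c.fp == 1

    def test_threshold_above_max_all_negative(self):
        m = _map_from([0.2, 0.6, 0.9])
        c = confusion_at_threshold(m, np.array([[0, 1, 1]]), 0.95)
        assert (c.tp, c.fp) == (0, 0) and c.tn == 1 and c.fn == 2

    def test_enumerated_example(self):
        m = _map_from([0.2, 0.6, 0.9])
        c = confusion_at_threshold(m, np.array([[0, 1, 1]]), 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_counts_cover_valid_pixels_only(self):
        m = _map_from([0.2, 0.6, 0.9, 0.4], valid=[1, 1, 0, 1])
        c = confusion_at_threshold(m, np.array([[0, 1, 1, 0]]), 0.5)
        assert c.total == 3


class TestMccDice:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0
        assert dice(ConfusionCounts(tp=5, fp=0, tn=5, fn=0)) == 1.0

    def test_worked_examples(self):
        c = ConfusionCounts(tp=3, fp=1, tn=4, fn=2)
        assert mcc(c) == pytest.approx(10 / np.sqrt(4 * 5 * 5 * 6), abs=1e-5)
        assert dice(c) == pytest.approx(6 / 9, abs=1e-5)

    def test_degenerate_conventions(self):
        assert mcc(ConfusionCounts(tp=5, fp=5, tn=0, fn=0)) == 0.0
        assert dice(ConfusionCounts(tp=0, fp=0, tn=3, fn=0)) == 1.0
        assert dice(ConfusionCounts(tp=0, fp=0, tn=0, fn=5)) == 0.0

    def test_matches_sklearn_on_random_rasters(self):
        from sklearn.metrics import f1_score, matthews_corrcoef

        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            truth = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            c = ConfusionCounts(
                tp=int(((pred == 1) & (truth == 1)).sum()),
                fp=int(((pred == 1) & (truth == 0)).sum()),
                tn=int(((pred == 0) & (truth == 0)).sum()),
                fn=int(((pred == 0) & (truth == 1)).sum()),
            )
            assert mcc(c) == pytest.approx(matthews_corrcoef(truth, pred), abs=1e-9)
            if truth.sum() or pred.sum():
                assert dice(c) == pytest.approx(
                    f1_score(truth, pred, zero_division=1.0), abs=1e-9
                )


class TestThresholdTuning:
    def test_specific_equals_brute_force(self):
        scores = np.array([0.1, 0.4, 0.45, 0.7, 0.9])
        truth = np.array([[0, 0, 1, 1, 1]])
        m = _map_from(scores)
        grid = np.linspace(0, 1, 11)
        t, v = tune_threshold_patient_specific(m, truth, "mcc", grid)
        values = [mcc(confusion_at_threshold(m, truth, g)) for g in grid]
        assert v == max(values)
        assert t == grid[int(np.argmax(values))]

    def test_perfectly_separated_picks_smallest_winning_threshold(self):
        m = _map_from([0.1, 0.2, 0.8, 0.9])
        truth = np.array([[0, 0, 1, 1]])
        t, v = tune_threshold_patient_specific(m, truth, "dice", np.linspace(0, 1, 21))
        assert v == 1.0
        # smallest grid point in the separating gap (0.2, 0.8]
        assert t == pytest.approx(0.25)

    def test_single_patient_generic_equals_specific(self):
        m = _map_from([0.2, 0.6, 0.9])
        truth = np.array([[0, 1, 1]])
        grid = default_threshold_grid()
        t_gen = tune_threshold_patient_generic([m], [truth], "mcc", grid)
        t_spec, _ = tune_threshold_patient_specific(m, truth, "mcc", grid)
        assert t_gen == t_spec

    def test_generic_between_symmetric_optima_and_dominated(self):
        rng = np.random.default_rng(4)
        grid = default_threshold_grid()
        # two patients with optimal separations at 0.3 and 0.7
        m1 = _map_from(np.concatenate([rng.uniform(0, 0.28, 50), rng.uniform(0.32, 1, 50)]))
        t1 = np.concatenate([np.zeros(50), np.ones(50)]).reshape(1, -1)
        m2 = _map_from(np.concatenate([rng.uniform(0, 0.68, 50), rng.uniform(0.72, 1, 50)]))
        t2 = np.concatenate([np.zeros(50), np.ones(50)]).reshape(1, -1)
        t_gen = tune_threshold_patient_generic([m1, m2], [t1, t2], "dice", grid)
        assert 0.28 < t_gen <= 0.72
        mean_at_gen = np.mean(
            [
                dice(confusion_at_threshold(m, t, t_gen))
                for m, t in [(m1, t1), (m2, t2)]
            ]
        )
        mean_specific = np.mean(
            [
                tune_threshold_patient_specific(m, t, "dice", grid)[1]
                for m, t in [(m1, t1), (m2, t2)]
            ]
        )
        assert mean_specific >= mean_at_gen


@pytest.fixture(scope="module")
def svm_lopocv(separable_cohort_6_module):
    manifest, data = separable_cohort_6_module
    folds = lopocv(
        manifest,
        ExperimentSetting("combined", "colon"),
        "rbf_svm",
        data,
        seed=0,
    )
    return folds


@pytest.fixture(scope="module")
def separable_cohort_6_module():
    cfg = synthetic.separable_config(
        n_colon=3, n_colon_no_cancer=1, n_eg=3, height=48, width=48, master_seed=31
    )
    return synthetic.simulate_cohort(cfg)


class TestLopocv:
    def test_each_patient_held_out_once(self, svm_lopocv):
        assert sorted(f.patient_id for f in svm_lopocv) == [
            "colon_01", "colon_02", "colon_03"
        ]

    def test_cancer_free_patient_has_no_auc(self, svm_lopocv):
        by_id = {f.patient_id: f for f in svm_lopocv}
        # the generator mirrors the clinical layout: first cancer-free slot
        assert by_id["colon_01"].roc_auc is None
        assert by_id["colon_02"].roc_auc is not None

    def test_policies_filled_and_specific_dominates(self, svm_lopocv):
        for f in svm_lopocv:
            for metric in ("mcc", "dice"):
                vals = getattr(f, metric)
                assert vals["patient_specific"] >= vals["patient_generic"] - 1e-12

    def test_too_few_patients_rejected(self, separable_cohort_6_module):
        manifest, data = separable_cohort_6_module
        single = type(manifest)(records=[manifest.records[0]], name="one")
        with pytest.raises(ValueError):
            lopocv(single, ExperimentSetting("colon", "colon"), "rbf_svm", data)


class TestCrossDataset:
    def test_overlapping_groups_rejected(self, separable_cohort_6_module):
        manifest, data = separable_cohort_6_module
        with pytest.raises(ValueError):
            cross_dataset_eval(manifest, "eg", "eg", "rbf_svm", data)

    def test_one_model_scores_all_test_patients(self, separable_cohort_6_module):
        manifest, data = separable_cohort_6_module
        folds = cross_dataset_eval(manifest, "eg", "colon", "rbf_svm", data, seed=0)
        assert len(folds) == 3
        by_id = {f.patient_id: f for f in folds}
        assert by_id["colon_01"].roc_auc is None  # cancer-free
        defined = [f.roc_auc for f in folds if f.roc_auc is not None]
        assert len(defined) == 2

    def test_shared_spectra_transfer_close_to_within_group(self, separable_cohort_6_module):
        manifest, data = separable_cohort_6_module
        cross = cross_dataset_eval(manifest, "colon", "eg", "rbf_svm", data, seed=0)
        within = lopocv(manifest, ExperimentSetting("eg", "eg"), "rbf_svm", data, seed=0)
        cross_mean = np.mean([f.roc_auc for f in cross if f.roc_auc is not None])
        within_mean = np.mean([f.roc_auc for f in within if f.roc_auc is not None])
        assert abs(cross_mean - within_mean) <= 0.1


class TestStatistics:
    def test_identical_vectors(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        a, b = rng.random(12), rng.random(12)
        t, p = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_nonzero_difference(self):
        t, p = paired_t_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert p == 0.0 and t == np.inf

    def test_aggregate_worked_example(self):
        m, s = aggregate_mean_sd([0.0, 1.0])
        assert m == 0.5
        assert s == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_aggregate_constant_vector(self):
        m, sd = aggregate_mean_sd([0.7, 0.7, 0.7])
        assert m == pytest.approx(0.7)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_aggregate_needs_two_values(self):
        with pytest.raises(ValueError):
            aggregate_mean_sd([1.0])
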
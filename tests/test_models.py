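"""Classifier construction, training recipes and whole-cube inference."""

import numpy as np
import pytest

from hsicad import hsio, models, nn, synthetic
from hsicad.evaluation import roc_auc
from hsicad.hsio import binarize_labels
from hsicad.models import (
    ClassicalModelSpec,
    CNNConfig,
    TrainingConfig,
    build_3dcnn,
    count_trainable_weights,
    load_checkpoint,
    predict_scores,
    save_checkpoint,
    train_3dcnn,
    train_classical,
)
from hsicad.preprocess import (
    PatchConfig,
    Sample,
    balance_downsample,
    extract_samples,
    snv_normalize_cube,
)


class TestArchitecture:
    def test_default_weight_checksum(self):
        assert count_trainable_weights(build_3dcnn()) == 32_232

    def test_conv_layer_weight_count(self):
        conv = nn.Conv3d(1, 20, (3, 3, 3))
        assert conv.n_weights() == 20 * 27 + 20

    def test_toy_linear_plan_closed_form(self):
        f = 17
        net = nn.Network([nn.Linear(f, 2)])
        assert count_trainable_weights(net) == 2 * f + 2

    def test_zero_network_on_zero_patch_gives_zero_logits(self):
        net = build_3dcnn()  # weights start at zero, biases zero
        out = net.forward(np.zeros((1, 1, 100, 5, 5)), train=False)
        np.testing.assert_array_equal(out, 0.0)

    def test_io_shape(self):
        net = build_3dcnn()
        net.init_kaiming(np.random.default_rng(0))
        out = net.forward(np.random.default_rng(1).normal(size=(3, 1, 100, 5, 5)),
                          train=False)
        assert out.shape == (3, 2)


def _gaussian_cluster_samples(n=200, d=100, sep=3.0, seed=0, with_patches=False):
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        label = i % 2
        spectrum = rng.normal(label * sep, 1.0, d)
        patch = None
        if with_patches:
            patch = np.broadcast_to(spectrum, (5, 5, d)).copy()
        samples.append(Sample("p", (i, 0), label, spectrum, patch))
    return samples


class TestClassical:
    def test_separable_clusters_perfect_training_auc(self):
        samples = _gaussian_cluster_samples()
        model = train_classical(ClassicalModelSpec("rbf_svm"), samples, seed=0)
        X = np.stack([s.spectrum for s in samples])
        y = np.array([s.label for s in samples])
        assert roc_auc(model.score_samples(X), y) == 1.0

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(1)
        samples = _gaussian_cluster_samples(n=300, sep=3.0, seed=1)
        y_perm = rng.permutation([s.label for s in samples])
        shuffled = [
            Sample(s.patient_id, s.pixel, int(y), s.spectrum)
            for s, y in zip(samples, y_perm)
        ]
        train, test = shuffled[:200], shuffled[200:]
        model = train_classical(ClassicalModelSpec("logistic_regression"), train, seed=1)
        X = np.stack([s.spectrum for s in test])
        y = np.array([s.label for s in test])
        assert 0.35 <= roc_auc(model.score_samples(X), y) <= 0.65

    def test_duplication_invariance_logreg(self):
        samples = _gaussian_cluster_samples(n=100, sep=2.0, seed=2)
        model_a = train_classical(ClassicalModelSpec("logistic_regression"), samples, seed=0)
        model_b = train_classical(
            ClassicalModelSpec("logistic_regression"), samples + samples, seed=0
        )
        X = np.stack([s.spectrum for s in samples])
        np.testing.assert_allclose(
            model_a.score_samples(X), model_b.score_samples(X), atol=5e-3
        )

    @pytest.mark.parametrize("kind", ["linear_svm", "mlp", "random_forest"])
    def test_all_kinds_fit_and_score_in_unit_interval(self, kind):
        samples = _gaussian_cluster_samples(n=80, sep=2.0, seed=3)
        model = train_classical(ClassicalModelSpec(kind), samples, seed=0)
        scores = model.score_samples(np.stack([s.spectrum for s in samples]))
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_one_class_rejected(self):
        samples = [s for s in _gaussian_cluster_samples(n=40) if s.label == 0]
        with pytest.raises(ValueError):
            train_classical(ClassicalModelSpec("rbf_svm"), samples, seed=0)


def _prepare(data, pid, window=5):
    cube, mask = data[pid]
    snv, degenerate = snv_normalize_cube(cube)
    samples = extract_samples(
        snv, mask, PatchConfig(window=window, bands=cube.n_bands),
        patient_id=pid, with_patches=True, exclude=degenerate,
    )
    return snv, degenerate, samples


class TestCnnTraining:
    def test_separable_cohort_recovery(self, separable_cohort_6):
        cfg, manifest, data = separable_cohort_6
        held_out = "eg_03"
        pool = [
            s for pid in data if pid != held_out for s in _prepare(data, pid)[2]
        ]
        balanced, _ = balance_downsample(pool, seed=0)
        tcfg = TrainingConfig(epochs=20, batch_size=512, seed=0)
        model = train_3dcnn(balanced, tcfg=tcfg)
        assert model.metadata["epochs_run"] == 20
        snv, degenerate, _ = _prepare(data, held_out)
        smap = predict_scores(model, snv, data[held_out][1], exclude=degenerate)
        truth = binarize_labels(data[held_out][1])
        v = smap.valid
        assert roc_auc(smap.scores[v], truth[v]) >= 0.95
        # separable patient: positives outscore negatives on average
        assert smap.scores[v & (truth == 1)].mean() > smap.scores[v & (truth == 0)].mean()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_null_cohort_chance_level(self, seed):
        cfg = synthetic.null_config(
            n_colon=3, n_colon_no_cancer=0, n_eg=3, height=64, width=64,
            master_seed=100 + seed,
        )
        _, data = synthetic.simulate_cohort(cfg)
        held_out = "colon_01"
        pool = [s for pid in data if pid != held_out for s in _prepare(data, pid)[2]]
        balanced, _ = balance_downsample(pool, seed=seed)
        model = train_3dcnn(
            balanced, tcfg=TrainingConfig(epochs=8, batch_size=512, seed=seed)
        )
        snv, degenerate, _ = _prepare(data, held_out)
        smap = predict_scores(model, snv, data[held_out][1], exclude=degenerate)
        truth = binarize_labels(data[held_out][1])
        v = smap.valid
        assert 0.4 <= roc_auc(smap.scores[v], truth[v]) <= 0.6

    def test_seeded_training_bit_reproducible(self):
        samples = _gaussian_cluster_samples(n=60, d=100, with_patches=True, seed=4)
        tcfg = TrainingConfig(epochs=3, batch_size=32, seed=7)
        m1 = train_3dcnn(samples, tcfg=tcfg)
        m2 = train_3dcnn(samples, tcfg=tcfg)
        X = models._patches_to_input(samples)
        np.testing.assert_array_equal(m1.score_samples(X), m2.score_samples(X))

    def test_one_class_rejected(self):
        samples = [s for s in _gaussian_cluster_samples(n=30, with_patches=True)
                   if s.label == 1]
        with pytest.raises(ValueError):
            train_3dcnn(samples, tcfg=TrainingConfig(epochs=1, seed=0))


class TestPredictScores:
    def _trained_on(self, data, pids, seed=0):
        pool = [s for pid in pids for s in _prepare(data, pid)[2]]
        balanced, _ = balance_downsample(pool, seed=seed)
        return train_3dcnn(
            balanced, tcfg=TrainingConfig(epochs=2, batch_size=256, seed=seed)
        )

    def test_inference_deterministic(self, separable_cohort_6):
        _, _, data = separable_cohort_6
        model = self._trained_on(data, ["colon_01", "colon_02"])
        snv, degenerate, _ = _prepare(data, "colon_03")
        s1 = predict_scores(model, snv, data["colon_03"][1], exclude=degenerate)
        s2 = predict_scores(model, snv, data["colon_03"][1], exclude=degenerate)
        np.testing.assert_array_equal(s1.scores, s2.scores)

    def test_validity_mask_equals_annotated(self, separable_cohort_6):
        _, _, data = separable_cohort_6
        model = self._trained_on(data, ["colon_01", "colon_02"])
        snv, degenerate, _ = _prepare(data, "eg_01")
        smap = predict_scores(model, snv, data["eg_01"][1], exclude=degenerate)
        expected = data["eg_01"][1].annotated() & ~degenerate
        np.testing.assert_array_equal(smap.valid, expected)
        s = smap.scores[smap.valid]
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_all_invalid_mask_gives_empty_scoremap(self, separable_cohort_6):
        _, _, data = separable_cohort_6
        model = self._trained_on(data, ["colon_01", "colon_02"])
        snv, _, _ = _prepare(data, "colon_03")
        empty = hsio.AnnotationMask(labels=np.zeros(snv.shape[:2], dtype=np.uint8))
        smap = predict_scores(model, snv, empty)
        assert not smap.valid.any()

    def test_normalization_tag_mismatch_rejected(self, separable_cohort_6):
        _, _, data = separable_cohort_6
        model = self._trained_on(data, ["colon_01", "colon_02"])
        raw_cube, mask = data["colon_03"]
        with pytest.raises(ValueError, match="normalization"):
            predict_scores(model, raw_cube, mask)


class TestCheckpoints:
    def test_roundtrip_scores_identical(self, tmp_path):
        samples = _gaussian_cluster_samples(n=40, with_patches=True, seed=5)
        model = train_3dcnn(samples, tcfg=TrainingConfig(epochs=2, batch_size=16, seed=0))
        path = save_checkpoint(model, tmp_path / "ckpt.npz")
        back = load_checkpoint(path)
        X = models._patches_to_input(samples)
        np.testing.assert_array_equal(model.score_samples(X), back.score_samples(X))
        assert back.normalization == "snv"

    def test_classical_has_no_checkpoint(self):
        samples = _gaussian_cluster_samples(n=40, seed=6)
        model = train_classical(ClassicalModelSpec("rbf_svm"), samples, seed=0)
        with pytest.raises(ValueError):
            save_checkpoint(model, "x.npz")
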
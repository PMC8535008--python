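"""Leave-one-patient-out evaluation, metrics and threshold policies.

One hypercube was acquired per patient, so leave-one-patient-out
cross-validation (LOPOCV) holds out each patient's image in turn, trains on
all remaining images, and scores the held-out image — the standard way to
measure generalization to a new patient with a small clinical cohort.

Threshold-dependent metrics (MCC, DICE) are reported under two policies: a
*patient-generic* threshold, one grid value maximizing the mean metric
across all test images, and a *patient-specific* threshold tuned per image.
The generic policy is tuned on the test images themselves (an oracle upper
bound on any fixed-threshold deployment); the gap between the two policies
quantifies how much per-patient threshold tuning could recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .hsio import (
    AnnotationMask,
    DatasetManifest,
    Hypercube,
    binarize_labels,
)
from .models import (
    ClassicalModelSpec,
    CNNConfig,
    ScoreMap,
    TrainedModel,
    TrainingConfig,
    predict_scores,
    train_3dcnn,
    train_classical,
)
from .preprocess import (
    PatchConfig,
    Sample,
    balance_downsample,
    extract_samples,
    snv_normalize_cube,
)

__all__ = [
    "ConfusionCounts",
    "ThresholdPolicy",
    "ExperimentSetting",
    "FoldResult",
    "UndefinedMetricError",
    "default_threshold_grid",
    "roc_auc",
    "confusion_at_threshold",
    "mcc",
    "dice",
    "tune_threshold_patient_specific",
    "tune_threshold_patient_generic",
    "apply_threshold_policies",
    "lopocv",
    "cross_dataset_eval",
    "paired_t_test",
    "aggregate_mean_sd",
]


class UndefinedMetricError(ValueError):
    """ROC-AUC is undefined when one class is absent."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def default_threshold_grid() -> np.ndarray:
    """201 evenly spaced candidate thresholds {0, 0.005, ..., 1}."""
    return np.linspace(0.0, 1.0, 201)


@dataclass(frozen=True)
class ThresholdPolicy:
    mode: str  # "patient_generic" | "patient_specific"
    metric: str  # "mcc" | "dice"
    grid: np.ndarray = field(default_factory=default_threshold_grid)

    def __post_init__(self) -> None:
        if self.mode not in ("patient_generic", "patient_specific"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.metric not in ("mcc", "dice"):
            raise ValueError(f"unknown metric {self.metric!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or np.any(np.diff(g) < 0) or g.min() < 0 or g.max() > 1:
            raise ValueError("grid must be a sorted non-empty subset of [0, 1]")


@dataclass(frozen=True)
class ExperimentSetting:
    """Which organ group(s) train the model and which one is tested.

    ``train_group`` is ``"colon"``, ``"eg"`` or ``"combined"``;
    ``test_group`` is ``"colon"`` or ``"eg"``.  ``cross_transfer`` marks
    the cross-dataset protocol (one model trained on the full train group,
    no fold-wise retraining).
    """

    train_group: str
    test_group: str
    cross_transfer: bool = False

    def __post_init__(self) -> None:
        if self.train_group not in ("colon", "eg", "combined"):
            raise ValueError(f"unknown train group {self.train_group!r}")
        if self.test_group not in ("colon", "eg"):
            raise ValueError(f"unknown test group {self.test_group!r}")
        if self.cross_transfer and self.train_group == self.test_group:
            raise ValueError("cross-transfer requires disjoint train and test groups")


@dataclass
class FoldResult:
    patient_id: str
    roc_auc: float | None  # None when the patient has no cancer pixels
    mcc: dict[str, float] = field(default_factory=dict)  # policy mode -> value
    dice: dict[str, float] = field(default_factory=dict)
    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)
    n_positive: int = 0
    n_negative: int = 0
    #: (patient_id, row, col) identities of the fold's training pool
    #: (populated on request; used to audit train/test disjointness)
    train_pixels: set | None = None


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware ROC-AUC via the rank-sum (Mann–Whitney) statistic.

    Equals (#concordant positive/negative pairs + ½·#tied pairs) divided
    by the total number of such pairs: the probability that a random
    cancer pixel is scored above a random healthy pixel.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC requires both classes present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def confusion_at_threshold(
    score_map: ScoreMap, truth: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Counts over valid pixels; a pixel is predicted positive iff score ≥ t."""
    valid = score_map.valid
    pred = score_map.scores[valid] >= threshold
    t = truth[valid] == 1
    return ConfusionCounts(
        tp=int((pred & t).sum()),
        fp=int((pred & ~t).sum()),
        tn=int((~pred & ~t).sum()),
        fn=int((~pred & t).sum()),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any root factor is zero."""
    denom2 = (
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if denom2 == 0.0:
        return 0.0
    return (float(c.tp) * c.tn - float(c.fp) * c.fn) / np.sqrt(denom2)


def dice(c: ConfusionCounts) -> float:
    """Sorensen–Dice / F1; 1 when there are no positives anywhere (0/0)."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


_METRICS = {"mcc": mcc, "dice": dice}


def _metric_curve(
    score_map: ScoreMap, truth: np.ndarray, metric: str, grid: np.ndarray
) -> np.ndarray:
    fn = _METRICS[metric]
    return np.array(
        [fn(confusion_at_threshold(score_map, truth, t)) for t in grid]
    )


def tune_threshold_patient_specific(
    score_map: ScoreMap, truth: np.ndarray, metric: str, grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Grid threshold maximizing the metric on this patient's image.

    Ties are broken toward the smallest threshold.  Returns
    ``(threshold, metric value)``.
    """
    grid = default_threshold_grid() if grid is None else np.asarray(grid, float)
    values = _metric_curve(score_map, truth, metric, grid)
    i = int(np.argmax(values))  # argmax returns the first (smallest-t) maximum
    return float(grid[i]), float(values[i])


def tune_threshold_patient_generic(
    score_maps: list[ScoreMap],
    truths: list[np.ndarray],
    metric: str,
    grid: np.ndarray | None = None,
) -> float:
    """Single grid threshold maximizing the unweighted mean metric across
    all test images; ties toward the smallest threshold."""
    if not score_maps:
        raise ValueError("need at least one patient")
    grid = default_threshold_grid() if grid is None else np.asarray(grid, float)
    curves = np.stack(
        [_metric_curve(m, t, metric, grid) for m, t in zip(score_maps, truths)]
    )
    mean_curve = curves.mean(axis=0)
    return float(grid[int(np.argmax(mean_curve))])


def apply_threshold_policies(
    folds: list[FoldResult],
    score_maps: dict[str, ScoreMap],
    truths: dict[str, np.ndarray],
    grid: np.ndarray | None = None,
) -> None:
    """Fill each fold's MCC/DICE under both policies (in place)."""
    grid = default_threshold_grid() if grid is None else np.asarray(grid, float)
    maps = [score_maps[f.patient_id] for f in folds]
    tr = [truths[f.patient_id] for f in folds]
    for metric in ("mcc", "dice"):
        t_gen = tune_threshold_patient_generic(maps, tr, metric, grid)
        for fold in folds:
            m, t = score_maps[fold.patient_id], truths[fold.patient_id]
            c = confusion_at_threshold(m, t, t_gen)
            getattr(fold, metric)["patient_generic"] = _METRICS[metric](c)
            fold.thresholds[("patient_generic", metric)] = t_gen
            t_spec, v_spec = tune_threshold_patient_specific(m, t, metric, grid)
            getattr(fold, metric)["patient_specific"] = v_spec
            fold.thresholds[("patient_specific", metric)] = t_spec


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

_GROUP_NAMES = {"colon": "colon", "eg": "esophagogastric"}


def _group_records(manifest: DatasetManifest, group: str):
    if group == "combined":
        return list(manifest.records)
    return manifest.group(_GROUP_NAMES[group])


def _prepare_patient(
    cube: Hypercube, mask: AnnotationMask, patient_id: str, with_patches: bool,
    window: int,
):
    snv_cube, degenerate = snv_normalize_cube(cube)
    samples = extract_samples(
        snv_cube,
        mask,
        PatchConfig(window=window, bands=cube.n_bands),
        patient_id=patient_id,
        with_patches=with_patches,
        exclude=degenerate,
    )
    return snv_cube, degenerate, samples


def _train_model(
    model_spec: ClassicalModelSpec | str,
    samples: list[Sample],
    seed: int,
    cnn_config: CNNConfig,
    training_config: TrainingConfig,
) -> TrainedModel:
    if model_spec == "cnn3d" or (
        isinstance(model_spec, str) and model_spec == "cnn3d"
    ):
        return train_3dcnn(samples, cnn_config, replace(training_config, seed=seed))
    spec = (
        model_spec
        if isinstance(model_spec, ClassicalModelSpec)
        else ClassicalModelSpec(kind=model_spec)
    )
    return train_classical(spec, samples, seed=seed)


def _is_cnn(model_spec) -> bool:
    return model_spec == "cnn3d"


def lopocv(
    manifest: DatasetManifest,
    setting: ExperimentSetting,
    model_spec: ClassicalModelSpec | str,
    data: dict[str, tuple[Hypercube, AnnotationMask]],
    seed: int = 0,
    cnn_config: CNNConfig = CNNConfig(),
    training_config: TrainingConfig = TrainingConfig(),
    grid: np.ndarray | None = None,
    record_training_pixels: bool = False,
) -> list[FoldResult]:
    """Leave-one-patient-out cross-validation in one experiment setting.

    For each patient of the test group: train on every other patient of
    the train group (class-balanced per fold), score the held-out image,
    and record ROC-AUC (absent for patients without cancer pixels).  After
    all folds, MCC and DICE are filled under both threshold policies.
    ``data`` maps patient id to its (raw cube, mask) pair.
    """
    test_records = _group_records(manifest, setting.test_group)
    if len(test_records) < 2:
        raise ValueError("LOPOCV needs at least two patients in the test group")
    train_records = _group_records(manifest, setting.train_group)
    for rec in test_records:
        if rec.patient_id not in data:
            raise ValueError(f"patient {rec.patient_id} missing from data")

    with_patches = _is_cnn(model_spec)
    window = cnn_config.window if with_patches else 1
    prepared = {}
    for rec in set(train_records + test_records):
        cube, mask = data[rec.patient_id]
        prepared[rec.patient_id] = _prepare_patient(
            cube, mask, rec.patient_id, with_patches, cnn_config.window
        )

    rng = np.random.default_rng(seed)
    folds: list[FoldResult] = []
    score_maps: dict[str, ScoreMap] = {}
    truths: dict[str, np.ndarray] = {}
    for rec in test_records:
        held_out = rec.patient_id
        pool = [
            s
            for r in train_records
            if r.patient_id != held_out
            for s in prepared[r.patient_id][2]
        ]
        fold_seed = int(rng.integers(2**31))
        balanced, _ = balance_downsample(pool, seed=fold_seed)
        model = _train_model(
            model_spec, balanced, fold_seed, cnn_config, training_config
        )
        snv_cube, degenerate, _ = prepared[held_out]
        _, mask = data[held_out]
        smap = predict_scores(
            model,
            snv_cube,
            mask,
            PatchConfig(window=cnn_config.window, bands=snv_cube.n_bands)
            if with_patches
            else None,
            exclude=degenerate,
        )
        smap = ScoreMap(scores=smap.scores, valid=smap.valid, patient_id=held_out)
        truth = binarize_labels(mask)
        score_maps[held_out] = smap
        truths[held_out] = truth
        v = smap.valid
        y = truth[v]
        n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
        try:
            auc = roc_auc(smap.scores[v], y)
        except UndefinedMetricError:
            auc = None
        folds.append(
            FoldResult(
                patient_id=held_out,
                roc_auc=auc,
                n_positive=n_pos,
                n_negative=n_neg,
                train_pixels={(s.patient_id, *s.pixel) for s in pool}
                if record_training_pixels
                else None,
            )
        )
    apply_threshold_policies(folds, score_maps, truths, grid)
    return folds


def cross_dataset_eval(
    manifest: DatasetManifest,
    train_group: str,
    test_group: str,
    model_spec: ClassicalModelSpec | str,
    data: dict[str, tuple[Hypercube, AnnotationMask]],
    seed: int = 0,
    cnn_config: CNNConfig = CNNConfig(),
    training_config: TrainingConfig = TrainingConfig(),
    grid: np.ndarray | None = None,
) -> list[FoldResult]:
    """Cross-dataset transfer: one model trained on the entire train group,
    every patient of the disjoint test group scored by that single model."""
    if train_group == test_group:
        raise ValueError("train and test groups must be disjoint")
    train_records = _group_records(manifest, train_group)
    test_records = _group_records(manifest, test_group)

    with_patches = _is_cnn(model_spec)
    prepared = {}
    for rec in train_records + test_records:
        cube, mask = data[rec.patient_id]
        prepared[rec.patient_id] = _prepare_patient(
            cube, mask, rec.patient_id, with_patches, cnn_config.window
        )
    pool = [s for r in train_records for s in prepared[r.patient_id][2]]
    rng = np.random.default_rng(seed)
    train_seed = int(rng.integers(2**31))
    balanced, _ = balance_downsample(pool, seed=train_seed)
    model = _train_model(model_spec, balanced, train_seed, cnn_config, training_config)

    folds: list[FoldResult] = []
    score_maps: dict[str, ScoreMap] = {}
    truths: dict[str, np.ndarray] = {}
    for rec in test_records:
        snv_cube, degenerate, _ = prepared[rec.patient_id]
        _, mask = data[rec.patient_id]
        smap = predict_scores(
            model,
            snv_cube,
            mask,
            PatchConfig(window=cnn_config.window, bands=snv_cube.n_bands)
            if with_patches
            else None,
            exclude=degenerate,
        )
        smap = ScoreMap(scores=smap.scores, valid=smap.valid, patient_id=rec.patient_id)
        truth = binarize_labels(mask)
        score_maps[rec.patient_id] = smap
        truths[rec.patient_id] = truth
        v = smap.valid
        y = truth[v]
        try:
            auc = roc_auc(smap.scores[v], y)
        except UndefinedMetricError:
            auc = None
        folds.append(
            FoldResult(
                patient_id=rec.patient_id,
                roc_auc=auc,
                n_positive=int((y == 1).sum()),
                n_negative=int((y == 0).sum()),
            )
        )
    apply_threshold_policies(folds, score_maps, truths, grid)
    return folds


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def paired_t_test(a, b) -> tuple[float, float]:
    """Paired two-tailed t-test on per-patient metric pairs.

    ``t = mean(d) / (sd(d)/√n)`` with sample sd; p from Student's t with
    n−1 degrees of freedom.  Degenerate cases: all differences zero →
    (0, 1); zero variance with nonzero mean → (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def aggregate_mean_sd(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n−1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    return float(v.mean()), float(v.std(ddof=1))
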
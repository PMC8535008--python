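"""Spectral-curve figures, prediction/error maps and results tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import FoldResult, aggregate_mean_sd
from .hsio import (
    AnnotationMask,
    DatasetManifest,
    Hypercube,
    LABEL_IGNORE,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    MASK_CODES,
    binarize_labels,
    load_patient,
    synthesize_rgb,
)
from .models import ScoreMap
from .preprocess import snv_normalize_cube

__all__ = [
    "SpectralSummary",
    "ErrorMap",
    "ERROR_CODES",
    "spectral_summary",
    "plot_spectral_summary",
    "render_maps",
    "results_tables",
]

# error-map codes
ERROR_CODES = {
    "correct": 0,
    "false_positive_as_cancer": 1,
    "false_negative_as_healthy": 2,
    "not_evaluated": 3,
}

# display palette: healthy purple, cancer red (the incorrect predicted class
# colors the error pixel)
_HEALTHY_RGB = np.array([128, 0, 128], dtype=np.uint8)
_CANCER_RGB = np.array([255, 0, 0], dtype=np.uint8)


@dataclass
class SpectralSummary:
    """Pooled per-wavelength mean and sd curve per tissue class."""

    wavelengths_nm: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_pixels: dict[str, int]
    normalized: str  # "raw" | "snv"


@dataclass
class ErrorMap:
    codes: np.ndarray  # H×W from ERROR_CODES


def spectral_summary(
    manifest: DatasetManifest,
    data: dict[str, tuple[Hypercube, AnnotationMask]] | None = None,
    classes: list[str] | None = None,
    normalized: bool = False,
    root: str | Path | None = None,
) -> SpectralSummary:
    """Pooled mean ± sd spectral curves over all annotated pixels per class.

    ``data`` supplies in-memory (cube, mask) pairs; otherwise cubes and
    masks are read from the manifest's file references.
    """
    classes = classes or [c for c in MASK_CODES.values() if c != "unannotated"]
    code_of = {v: k for k, v in MASK_CODES.items()}
    acc: dict[str, list[np.ndarray]] = {c: [] for c in classes}
    wavelengths = None
    for rec in manifest.records:
        if data is not None:
            cube, mask = data[rec.patient_id]
        else:
            cube, mask = load_patient(rec, root)
        if normalized and cube.normalized == "raw":
            cube, _ = snv_normalize_cube(cube)
        wavelengths = cube.grid.as_array()
        for c in classes:
            sel = mask.labels == code_of[c]
            if sel.any():
                acc[c].append(cube.values[sel].astype(np.float64))
    mean, sd, n_pixels = {}, {}, {}
    for c in classes:
        if not acc[c]:
            raise ValueError(f"class {c!r} has no annotated pixels in the cohort")
        pooled = np.concatenate(acc[c], axis=0)
        mean[c] = pooled.mean(axis=0)
        sd[c] = pooled.std(axis=0)
        n_pixels[c] = pooled.shape[0]
    return SpectralSummary(
        wavelengths_nm=wavelengths,
        mean=mean,
        sd=sd,
        n_pixels=n_pixels,
        normalized="snv" if normalized else "raw",
    )


def plot_spectral_summary(summary: SpectralSummary, path: str | Path) -> Path:
    """Mean curves with ±1 sd bands, one panel, PNG output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cls, m in summary.mean.items():
        (line,) = ax.plot(summary.wavelengths_nm, m, label=f"{cls} (n={summary.n_pixels[cls]})")
        ax.fill_between(
            summary.wavelengths_nm,
            m - summary.sd[cls],
            m + summary.sd[cls],
            alpha=0.2,
            color=line.get_color(),
        )
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(
        "relative reflectance" if summary.normalized == "raw" else "SNV-normalized reflectance"
    )
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def render_maps(
    cube: Hypercube,
    mask: AnnotationMask,
    score_map: ScoreMap,
    threshold: float,
    path: str | Path | None = None,
) -> tuple[np.ndarray, np.ndarray, ErrorMap]:
    """RGB image, thresholded prediction image, and error map.

    Error pixels are colored by the *incorrectly predicted* class: a
    healthy pixel predicted as cancer shows the cancer color, and vice
    versa.  When ``path`` is given, a four-panel PNG (RGB / ground truth /
    prediction / error) is written.
    """
    if cube.shape[:2] != mask.shape or score_map.scores.shape != mask.shape:
        raise ValueError("cube, mask and score map are not aligned")
    rgb = synthesize_rgb(cube)
    truth = binarize_labels(mask)
    valid = score_map.valid & (truth != LABEL_IGNORE)

    pred_img = np.zeros(mask.shape + (3,), dtype=np.uint8)
    pred_pos = score_map.scores >= threshold
    pred_img[valid & pred_pos] = _CANCER_RGB
    pred_img[valid & ~pred_pos] = _HEALTHY_RGB

    codes = np.full(mask.shape, ERROR_CODES["not_evaluated"], dtype=np.uint8)
    codes[valid] = ERROR_CODES["correct"]
    codes[valid & pred_pos & (truth == LABEL_NEGATIVE)] = ERROR_CODES[
        "false_positive_as_cancer"
    ]
    codes[valid & ~pred_pos & (truth == LABEL_POSITIVE)] = ERROR_CODES[
        "false_negative_as_healthy"
    ]

    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        truth_img = np.zeros(mask.shape + (3,), dtype=np.uint8)
        truth_img[truth == LABEL_NEGATIVE] = _HEALTHY_RGB
        truth_img[truth == LABEL_POSITIVE] = _CANCER_RGB
        err_img = np.zeros(mask.shape + (3,), dtype=np.uint8)
        err_img[codes == ERROR_CODES["false_positive_as_cancer"]] = _CANCER_RGB
        err_img[codes == ERROR_CODES["false_negative_as_healthy"]] = _HEALTHY_RGB
        fig, axes = plt.subplots(1, 4, figsize=(12, 3.2))
        for ax, img, title in zip(
            axes,
            (rgb, truth_img, pred_img, err_img),
            ("RGB", "ground truth", "prediction", "error map"),
        ):
            ax.imshow(img)
            ax.set_title(title, fontsize=9)
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    return rgb, pred_img, ErrorMap(codes=codes)


def _fmt(x: float | None) -> str:
    return "/" if x is None else f"{x:.2f}"


def results_tables(
    fold_results: dict[str, list[FoldResult]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient and aggregate results tables across experiment settings.

    ``fold_results`` maps a setting label (e.g. ``"colon→colon"``) to its
    fold list.  The per-patient table has one AUC column per setting with
    ``"/"`` for patients without cancer pixels; the aggregate table
    carries ``mean ± sd`` strings for AUC and for MCC/DICE under both
    threshold policies.  Aggregates are always recomputed from the
    per-patient values shown.
    """
    if not fold_results:
        raise ValueError("need at least one evaluated setting")
    per_patient = {}
    for label, folds in fold_results.items():
        per_patient[label] = {f.patient_id: _fmt(f.roc_auc) for f in folds}
    per_patient_df = pd.DataFrame(per_patient)

    rows = []
    for label, folds in fold_results.items():
        aucs = [f.roc_auc for f in folds if f.roc_auc is not None]
        row: dict[str, str] = {"setting": label}
        if len(aucs) >= 2:
            m, s = aggregate_mean_sd(aucs)
            row["roc_auc"] = f"{m:.2f} ± {s:.3f}"
        else:
            row["roc_auc"] = "/"
        for metric in ("mcc", "dice"):
            for policy in ("patient_generic", "patient_specific"):
                vals = [getattr(f, metric).get(policy) for f in folds]
                vals = [v for v in vals if v is not None]
                key = f"{metric}_{policy}"
                if len(vals) >= 2:
                    m, s = aggregate_mean_sd(vals)
                    row[key] = f"{m:.2f} ± {s:.2f}"
                else:
                    row[key] = "/"
        rows.append(row)
    aggregate_df = pd.DataFrame(rows).set_index("setting")
    return per_patient_df, aggregate_df
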
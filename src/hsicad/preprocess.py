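"""Spectral normalization and labeled-sample extraction.

Standard normal variate (SNV) normalization rescales each pixel spectrum
independently to zero mean and unit standard deviation.  Additive offsets
and multiplicative gains — the dominant nuisance effects from tissue
surface orientation and light scattering — are exactly removed, which is
why it is the canonical preprocessing for reflectance spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsio import AnnotationMask, Hypercube, LABEL_IGNORE, binarize_labels

__all__ = [
    "PatchConfig",
    "Sample",
    "BalanceReport",
    "DegenerateSpectrumError",
    "snv_normalize",
    "snv_normalize_cube",
    "extract_samples",
    "extract_patch",
    "balance_downsample",
    "split_train_validation",
    "inverse_frequency_weights",
]


class DegenerateSpectrumError(ValueError):
    """A constant spectrum has zero variance and no SNV transform."""


@dataclass(frozen=True)
class PatchConfig:
    """Geometry of the spatial window fed to the patch classifier."""

    window: int = 5
    pad_mode: str = "zero"
    bands: int = 100

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.pad_mode != "zero":
            raise ValueError("only zero padding is supported")


@dataclass
class Sample:
    """One labeled pixel: its spectrum and (optionally) its spatial patch."""

    patient_id: str
    pixel: tuple[int, int]
    label: int  # LABEL_NEGATIVE or LABEL_POSITIVE
    spectrum: np.ndarray
    patch: np.ndarray | None = None


@dataclass(frozen=True)
class BalanceReport:
    counts_before: dict[int, int]
    counts_after: dict[int, int]
    s: int
    seed: int


def snv_normalize(spectrum: np.ndarray) -> np.ndarray:
    """SNV-normalize one spectrum: ``(x - mean(x)) / sd(x)`` (population sd)."""
    x = np.asarray(spectrum, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("spectrum must be a 1-D vector of length >= 2")
    sd = x.std()
    if sd == 0:
        raise DegenerateSpectrumError("constant spectrum has zero variance")
    return (x - x.mean()) / sd


def snv_normalize_cube(cube: Hypercube) -> tuple[Hypercube, np.ndarray]:
    """SNV-normalize every pixel spectrum of a cube independently.

    Returns the normalized cube (flagged ``"snv"``) and an H×W boolean
    raster marking degenerate (constant-spectrum) pixels, which are left
    as zeros and should be excluded from training and scored as invalid.
    """
    if cube.normalized == "snv":
        raise ValueError("cube is already SNV-normalized")
    v = cube.values.astype(np.float64)
    mean = v.mean(axis=2, keepdims=True)
    sd = v.std(axis=2, keepdims=True)
    degenerate = sd[:, :, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (v - mean) / safe_sd
    out[degenerate] = 0.0
    return (
        Hypercube(values=out.astype(np.float32), grid=cube.grid, normalized="snv"),
        degenerate,
    )


def extract_patch(values: np.ndarray, row: int, col: int, window: int) -> np.ndarray:
    """window×window×L block centered on (row, col), zero-padded at borders."""
    h, w, L = values.shape
    r = window // 2
    patch = np.zeros((window, window, L), dtype=values.dtype)
    r0, r1 = max(0, row - r), min(h, row + r + 1)
    c0, c1 = max(0, col - r), min(w, col + r + 1)
    patch[r0 - (row - r) : r1 - (row - r), c0 - (col - r) : c1 - (col - r)] = values[
        r0:r1, c0:c1
    ]
    return patch


def extract_samples(
    cube: Hypercube,
    mask: AnnotationMask,
    cfg: PatchConfig | None = None,
    patient_id: str = "",
    with_patches: bool = False,
    exclude: np.ndarray | None = None,
) -> list[Sample]:
    """One :class:`Sample` per annotated pixel of ``mask``.

    The sample's spectrum is the cube's pixel spectrum; when
    ``with_patches`` is set, the window×window×L sub-volume centered on the
    pixel is attached (out-of-image positions zero-filled).  ``exclude``
    optionally masks out pixels (e.g. degenerate spectra).
    """
    cfg = cfg or PatchConfig(bands=cube.n_bands)
    if cube.shape[:2] != mask.shape:
        raise ValueError("cube and mask are not spatially aligned")
    if cfg.bands != cube.n_bands:
        raise ValueError("patch config band count does not match cube")
    if cfg.window > 2 * min(cube.shape[:2]):
        raise ValueError("patch window larger than the image")
    labels = binarize_labels(mask)
    keep = labels != LABEL_IGNORE
    if exclude is not None:
        keep &= ~exclude
    samples = []
    for row, col in zip(*np.nonzero(keep)):
        samples.append(
            Sample(
                patient_id=patient_id,
                pixel=(int(row), int(col)),
                label=int(labels[row, col]),
                spectrum=cube.values[row, col].copy(),
                patch=extract_patch(cube.values, int(row), int(col), cfg.window)
                if with_patches
                else None,
            )
        )
    return samples


def balance_downsample(
    samples: list[Sample], seed: int
) -> tuple[list[Sample], BalanceReport]:
    """Equalize class counts by uniform downsampling without replacement.

    Every class is reduced to S, the size of the least-represented class.
    Retained samples are kept verbatim, in their original relative order.
    """
    rng = np.random.default_rng(seed)
    labels = np.array([s.label for s in samples])
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("balancing requires at least two classes present")
    counts_before = {c: int((labels == c).sum()) for c in classes}
    s_min = min(counts_before.values())
    keep_idx: list[int] = []
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        if idx.size > s_min:
            idx = rng.choice(idx, size=s_min, replace=False)
        keep_idx.extend(idx.tolist())
    keep_idx.sort()
    kept = [samples[i] for i in keep_idx]
    report = BalanceReport(
        counts_before=counts_before,
        counts_after={c: s_min for c in classes},
        s=s_min,
        seed=seed,
    )
    return kept, report


def split_train_validation(
    samples: list[Sample], fraction: float = 0.10, seed: int = 0
) -> tuple[list[Sample], list[Sample]]:
    """Disjoint, exhaustive uniform-random split; validation size = round(f·n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    n_val = int(round(fraction * n))
    val_idx = set(rng.choice(n, size=n_val, replace=False).tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val


def inverse_frequency_weights(counts: dict[int, int]) -> dict[int, float]:
    """Per-class weights ∝ 1/count, normalized to sum to the class count."""
    if any(c <= 0 for c in counts.values()):
        raise ValueError("all class counts must be positive")
    inv = {k: 1.0 / v for k, v in counts.items()}
    scale = len(counts) / sum(inv.values())
    return {k: v * scale for k, v in inv.items()}
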
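"""Synthetic two-organ hyperspectral cohorts.

Generates annotated colon and esophagogastric (EG) cohorts with the
statistical structure the analysis pipeline assumes: smooth class-mean
reflectance curves with physiologically placed absorption features
(hemoglobin around 540/575 nm, fat near 740 nm, water near 980 nm),
patient-level additive/multiplicative scatter that SNV removes exactly,
within-class smooth spectral jitter, independent pixel noise, and
spatially contiguous minority tumor regions inside a sparsely annotated
ROI — mirroring how clinical cubes are annotated by region of interest
rather than wall-to-wall.

The cancer-vs-healthy contrast is controlled by a single separation
parameter ``delta``: the cancer mean curve is the organ's healthy curve
plus ``delta`` times a fixed difference profile, so ``delta = 0`` yields a
null cohort in which no classifier should beat chance.

Spectral shapes are phenomenological Gaussian-bump mixtures, not
radiative-transfer models; the pipeline only needs class-separable smooth
curves with realistic nuisance structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hsio import (
    AnnotationMask,
    DatasetManifest,
    Hypercube,
    PatientRecord,
    WavelengthGrid,
    default_grid,
    write_cube,
    write_manifest,
    write_mask,
)

__all__ = [
    "GaussianBump",
    "ClassSpectrumModel",
    "PatientEffects",
    "CohortConfig",
    "default_spectrum_model",
    "class_mean_spectrum",
    "simulate_patient",
    "simulate_cohort",
    "separable_config",
    "null_config",
]


@dataclass(frozen=True)
class GaussianBump:
    center_nm: float
    width_nm: float
    amplitude: float

    def __call__(self, wl: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wl - self.center_nm) / self.width_nm) ** 2)


@dataclass(frozen=True)
class ClassSpectrumModel:
    """Per-class mean-curve parameters and intra-class variability.

    ``healthy``: organ-class name -> (baseline, slope per 1000 nm, bumps).
    ``cancer_delta_profile``: bumps added (scaled by ``delta``) to the
    organ's healthy curve to form the cancer curve; ``cancer_slope_delta``
    likewise tilts it.
    """

    healthy: dict[str, tuple[float, float, tuple[GaussianBump, ...]]]
    cancer_delta_profile: tuple[GaussianBump, ...]
    cancer_slope_delta: float
    jitter_sd: float = 0.04  # smooth within-class spectral jitter

    def classes(self) -> list[str]:
        return list(self.healthy) + ["cancer"]


def default_spectrum_model(jitter_sd: float = 0.04) -> ClassSpectrumModel:
    """Default tissue-class curves over 500–1000 nm.

    Healthy mucosa: rising reflectance with hemoglobin absorption dips at
    540/575 nm; the three healthy classes differ modestly in baseline and
    NIR slope.  The cancer difference profile raises water (980 nm) and
    fat (740 nm) features and shifts the hemoglobin region, consistent
    with the higher perfusion and water content of tumor tissue.
    """
    hb = (
        GaussianBump(540.0, 18.0, -0.10),
        GaussianBump(575.0, 15.0, -0.09),
    )
    return ClassSpectrumModel(
        healthy={
            "healthy_colon": (0.45, 0.20, hb + (GaussianBump(920.0, 60.0, -0.04),)),
            "healthy_stomach": (0.50, 0.16, hb + (GaussianBump(900.0, 70.0, -0.03),)),
            "healthy_esophagus": (0.42, 0.23, hb + (GaussianBump(940.0, 55.0, -0.05),)),
        },
        cancer_delta_profile=(
            GaussianBump(740.0, 40.0, 0.06),   # fat feature
            GaussianBump(980.0, 35.0, -0.08),  # water absorption
            GaussianBump(560.0, 25.0, 0.05),   # perfusion shift
        ),
        cancer_slope_delta=-0.05,
        jitter_sd=jitter_sd,
    )


@dataclass(frozen=True)
class PatientEffects:
    """Per-patient nuisance transform ``x -> (a + b·x)·(1 + tilt·λ̂)``.

    With ``tilt = 0`` the transform is affine per pixel and SNV removes it
    exactly; a nonzero tilt emulates residual wavelength-dependent gain
    that SNV cannot fully remove.
    """

    offset: float
    gain: float
    tilt: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale cohort layout and nuisance magnitudes.

    Defaults mirror the clinical cohorts: 12 colon patients of whom 2 are
    cancer-free, 10 EG patients, cancer occupying a small minority
    (~9%) of annotated pixels, at a desk-scale 64×64 image size.
    """

    n_colon: int = 12
    n_colon_no_cancer: int = 2
    n_eg: int = 10
    height: int = 64
    width: int = 64
    n_bands: int = 100
    annotated_fraction: float = 0.35
    cancer_fraction: float = 0.09  # of annotated pixels
    blob_count_range: tuple[int, int] = (1, 3)
    noise_sd: float = 0.02
    jitter_sd: float = 0.04
    delta: float = 1.0
    patient_offset_sd: float = 0.05
    patient_log_gain_sd: float = 0.15
    patient_tilt_sd: float = 0.02
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cancer_fraction < 1:
            raise ValueError("cancer fraction must be in (0, 1)")
        if not 0 < self.annotated_fraction <= 1:
            raise ValueError("annotated fraction must be in (0, 1]")
        if min(self.height, self.width, self.n_bands) < 1:
            raise ValueError("all sizes must be positive")
        if self.n_colon < 0 or self.n_eg < 0 or self.n_colon + self.n_eg < 1:
            raise ValueError("cohort must contain at least one patient")
        if self.n_colon_no_cancer > self.n_colon:
            raise ValueError("more cancer-free patients than colon patients")


def separable_config(**overrides) -> CohortConfig:
    """A strongly separable low-noise variant (for recovery checks)."""
    base = dict(delta=2.0, noise_sd=0.01, jitter_sd=0.02, patient_tilt_sd=0.0)
    base.update(overrides)
    return CohortConfig(**base)


def null_config(**overrides) -> CohortConfig:
    """The null cohort: cancer and healthy curves identical (delta = 0)."""
    overrides.setdefault("delta", 0.0)
    return CohortConfig(**overrides)


def class_mean_spectrum(
    model: ClassSpectrumModel,
    tissue_class: str,
    grid: WavelengthGrid,
    organ_class: str = "healthy_colon",
    delta: float = 1.0,
) -> np.ndarray:
    """Mean reflectance curve of a class on ``grid``.

    ``tissue_class`` is one of the healthy classes or ``"cancer"``; for
    cancer, ``organ_class`` names the healthy curve the difference profile
    is added to, scaled by ``delta``.  Raises if the resulting curve is not
    strictly positive (a non-physical configuration).
    """
    wl = grid.as_array()
    lam = (wl - wl[0]) / 1000.0  # slope parameterized per 1000 nm
    if tissue_class == "cancer":
        base, slope, bumps = model.healthy[organ_class]
        curve = base + slope * lam * 1000.0 / (wl[-1] - wl[0])
        for bump in bumps:
            curve = curve + bump(wl)
        for bump in model.cancer_delta_profile:
            curve = curve + delta * bump(wl)
        curve = curve + delta * model.cancer_slope_delta * lam * 1000.0 / (wl[-1] - wl[0])
    else:
        base, slope, bumps = model.healthy[tissue_class]
        curve = base + slope * lam * 1000.0 / (wl[-1] - wl[0])
        for bump in bumps:
            curve = curve + bump(wl)
    if np.any(curve <= 0):
        raise ValueError(f"mean curve for {tissue_class!r} is not strictly positive")
    return curve


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _ellipse_mask(
    h: int, w: int, center: tuple[float, float], radii: tuple[float, float], angle: float
) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w]
    dr, dc = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _annotated_region(h: int, w: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """One large random ellipse covering ≈ ``fraction`` of the image."""
    target = fraction * h * w
    # area = pi*r1*r2; draw aspect then solve for scale
    aspect = rng.uniform(0.6, 1.6)
    r1 = np.sqrt(target / (np.pi * aspect))
    r2 = aspect * r1
    center = (
        rng.uniform(0.35 * h, 0.65 * h),
        rng.uniform(0.35 * w, 0.65 * w),
    )
    return _ellipse_mask(h, w, center, (r1, r2), rng.uniform(0, np.pi))


def _place_tumor_blobs(
    annotated: np.ndarray,
    target_fraction: float,
    blob_count_range: tuple[int, int],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """1–3 contiguous elliptical tumor blobs totalling ≈ target fraction
    of the annotated region."""
    h, w = annotated.shape
    n_annot = int(annotated.sum())
    target_px = target_fraction * n_annot
    k = int(rng.integers(blob_count_range[0], blob_count_range[1] + 1))
    rows, cols = np.nonzero(annotated)
    tumor = np.zeros_like(annotated)
    for _ in range(k):
        per_blob = target_px / k
        aspect = rng.uniform(0.6, 1.6)
        r1 = np.sqrt(per_blob / (np.pi * aspect))
        r2 = aspect * r1
        placed = False
        for _ in range(max_tries):
            j = int(rng.integers(rows.size))
            blob = _ellipse_mask(h, w, (float(rows[j]), float(cols[j])), (r1, r2),
                                 rng.uniform(0, np.pi))
            # accept if the blob lies mostly inside the annotated region
            if (blob & annotated).sum() >= 0.8 * blob.sum() and blob.sum() > 0:
                tumor |= blob & annotated
                placed = True
                break
        if not placed:
            raise ValueError("could not place tumor blobs inside the annotated region")
    return tumor


def _smooth_jitter(
    n: int, L: int, sd: float, rng: np.random.Generator, scale_bands: int = 10
) -> np.ndarray:
    """``n`` smooth random spectral perturbations with pointwise sd = ``sd``.

    White noise smoothed by a Gaussian kernel normalized to unit energy,
    so the pointwise standard deviation is exactly ``sd`` while adjacent
    bands are strongly correlated (correlation length ≈ ``scale_bands``).
    """
    kernel = np.exp(
        -0.5 * (np.arange(-2 * scale_bands, 2 * scale_bands + 1) / scale_bands) ** 2
    )
    kernel /= np.sqrt((kernel**2).sum())
    raw = rng.normal(0.0, 1.0, (n, L + kernel.size - 1))
    out = np.zeros((n, L))
    for t, k in enumerate(kernel):
        out += k * raw[:, t : t + L]
    return sd * out


# ---------------------------------------------------------------------------
# Patient / cohort simulation
# ---------------------------------------------------------------------------

_CLASS_CODE = {"healthy_colon": 1, "healthy_stomach": 2, "healthy_esophagus": 3, "cancer": 4}


def simulate_patient(
    cfg: CohortConfig,
    model: ClassSpectrumModel,
    organ_group: str,
    has_cancer: bool,
    seed: int,
    patient_id: str = "p0",
) -> tuple[Hypercube, AnnotationMask, PatientRecord]:
    """Simulate one patient's cube, mask and clinical record.

    The mask annotates one ROI-style region with the organ-appropriate
    healthy class(es) plus, if ``has_cancer``, contiguous elliptical tumor
    blobs; every pixel spectrum is the patient-effects transform of its
    class mean plus smooth spectral jitter and independent pixel noise.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    h, w, L = cfg.height, cfg.width, cfg.n_bands
    grid = default_grid(L)
    wl = grid.as_array()
    lam_hat = (wl - wl.mean()) / (wl[-1] - wl[0])

    annotated = _annotated_region(h, w, cfg.annotated_fraction, rng)
    labels = np.zeros((h, w), dtype=np.uint8)
    if organ_group == "colon":
        labels[annotated] = _CLASS_CODE["healthy_colon"]
        organ_class = "healthy_colon"
    else:
        # split the healthy ROI into stomach and esophagus by a random line
        rows, cols = np.mgrid[0:h, 0:w]
        theta = rng.uniform(0, np.pi)
        split = (np.cos(theta) * rows + np.sin(theta) * cols) > (
            np.cos(theta) * h / 2 + np.sin(theta) * w / 2 + rng.normal(0, h / 8)
        )
        labels[annotated & split] = _CLASS_CODE["healthy_stomach"]
        labels[annotated & ~split] = _CLASS_CODE["healthy_esophagus"]
        organ_class = "healthy_stomach" if rng.random() < 0.5 else "healthy_esophagus"
    if has_cancer:
        tumor = _place_tumor_blobs(annotated, cfg.cancer_fraction,
                                   cfg.blob_count_range, rng)
        labels[tumor] = _CLASS_CODE["cancer"]

    effects = PatientEffects(
        offset=float(rng.normal(0.0, cfg.patient_offset_sd)),
        gain=float(np.exp(rng.normal(0.0, cfg.patient_log_gain_sd))),
        tilt=float(rng.normal(0.0, cfg.patient_tilt_sd)) if cfg.patient_tilt_sd > 0 else 0.0,
    )

    mean_curves = {
        code: class_mean_spectrum(
            model,
            name,
            grid,
            organ_class=organ_class,
            delta=cfg.delta,
        )
        for name, code in _CLASS_CODE.items()
    }

    # background (unannotated) pixels carry a generic tissue-like spectrum
    background = 0.5 * (mean_curves[1] + mean_curves[2])
    curve_table = np.stack([background] + [mean_curves[c] for c in (1, 2, 3, 4)])
    base = curve_table[labels.reshape(-1)]  # (H·W, L)
    spectra = base + (
        _smooth_jitter(h * w, L, cfg.jitter_sd, rng) if cfg.jitter_sd > 0 else 0.0
    )
    tilt_factor = 1.0 + effects.tilt * lam_hat
    spectra = (effects.offset + effects.gain * spectra) * tilt_factor
    if cfg.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, cfg.noise_sd, spectra.shape)
    values = spectra.reshape(h, w, L)

    cube = Hypercube(values=values, grid=grid, normalized="raw")
    mask = AnnotationMask(labels=labels)
    record = PatientRecord(
        patient_id=patient_id,
        organ_group=organ_group,
        cube_path=f"{patient_id}.hdr",
        mask_path=f"{patient_id}.png",
        age=int(rng.integers(50, 85)),
        sex="m" if rng.random() < 0.7 else "f",
        tissue_location=organ_group if organ_group == "colon" else "G-E junction",
        t_classification=("pT" + str(int(rng.integers(1, 5)))) if has_cancer else "none",
        grade=("G" + str(int(rng.integers(1, 4)))) if has_cancer else "",
    )
    return cube, mask, record


def simulate_cohort(
    cfg: CohortConfig,
    model: ClassSpectrumModel | None = None,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, dict[str, tuple[Hypercube, AnnotationMask]]]:
    """Simulate the full two-organ cohort.

    Returns the manifest and an in-memory ``{patient_id: (cube, mask)}``
    mapping; when ``out_dir`` is given, also writes cubes (ENVI), masks
    (indexed PNG) and the manifest CSV there, byte-reproducibly for a
    given master seed.
    """
    model = model or default_spectrum_model(jitter_sd=cfg.jitter_sd)
    seed_seq = np.random.SeedSequence(cfg.master_seed)
    n_total = cfg.n_colon + cfg.n_eg
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_total)]

    records = []
    data: dict[str, tuple[Hypercube, AnnotationMask]] = {}
    idx = 0
    # mirror the clinical layout: the cancer-free colon patients are the 2nd and 6th
    no_cancer_positions = {1, 5} if cfg.n_colon >= 6 and cfg.n_colon_no_cancer == 2 else set(
        range(cfg.n_colon_no_cancer)
    )
    for i in range(cfg.n_colon):
        pid = f"colon_{i + 1:02d}"
        cube, mask, rec = simulate_patient(
            cfg,
            model,
            "colon",
            has_cancer=i not in no_cancer_positions,
            seed=child_seeds[idx],
            patient_id=pid,
        )
        records.append(rec)
        data[pid] = (cube, mask)
        idx += 1
    for i in range(cfg.n_eg):
        pid = f"eg_{i + 1:02d}"
        cube, mask, rec = simulate_patient(
            cfg, model, "esophagogastric", has_cancer=True,
            seed=child_seeds[idx], patient_id=pid,
        )
        records.append(rec)
        data[pid] = (cube, mask)
        idx += 1

    manifest = DatasetManifest(records=records, name=f"synthetic_seed{cfg.master_seed}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            cube, mask = data[rec.patient_id]
            write_cube(cube, out_dir / rec.cube_path)
            write_mask(mask, out_dir / rec.mask_path)
        write_manifest(manifest, out_dir / "manifest.csv")
    return manifest, data
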
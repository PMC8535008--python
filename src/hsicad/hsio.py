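"""Data model and file I/O for hypercubes, annotation masks and patient manifests.

A hypercube is an H×W×L raster of relative reflectance bound to a grid of
band-center wavelengths (here 100 bands spanning 500–1000 nm, the range of
visible/NIR push-broom cameras used in open surgery).  Cubes are stored on
disk as an ENVI text header (``.hdr``) paired with a raw band-sequential
float32 raster (``.raw``).  Annotation masks are indexed PNG images whose
palette codes identify the annotated tissue class; manifests are plain CSV.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "AnnotationMask",
    "PatientRecord",
    "DatasetManifest",
    "FormatError",
    "MASK_CODES",
    "LABEL_IGNORE",
    "LABEL_NEGATIVE",
    "LABEL_POSITIVE",
    "default_grid",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "synthesize_rgb",
    "class_proportions",
    "binarize_labels",
]

#: annotation palette: code -> class name
MASK_CODES: Mapping[int, str] = {
    0: "unannotated",
    1: "healthy_colon",
    2: "healthy_stomach",
    3: "healthy_esophagus",
    4: "cancer",
}

# binarized label codes (cancer-vs-healthy task)
LABEL_IGNORE = -1
LABEL_NEGATIVE = 0
LABEL_POSITIVE = 1

# display palette for indexed-PNG masks, mirroring the usual annotation colors
# (purple healthy colon, blue stomach, green esophagus, red cancer)
MASK_PALETTE = {
    0: (0, 0, 0),
    1: (128, 0, 128),
    2: (0, 0, 255),
    3: (0, 200, 0),
    4: (255, 0, 0),
}


class FormatError(ValueError):
    """Raised when an on-disk cube or mask is internally inconsistent."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    wavelengths_nm: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", tuple(float(x) for x in w))

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band whose center is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.as_array() - wavelength_nm)))


def default_grid(n_bands: int = 100, lo: float = 500.0, hi: float = 1000.0) -> WavelengthGrid:
    """The default camera model: ``n_bands`` evenly spaced centers over [lo, hi] nm."""
    return WavelengthGrid(tuple(np.linspace(lo, hi, n_bands)))


@dataclass
class Hypercube:
    """H×W×L relative-reflectance raster with its wavelength grid.

    ``normalized`` is ``"raw"`` for reflectance as acquired and ``"snv"``
    after per-pixel standard-normal-variate normalization.
    """

    values: np.ndarray
    grid: WavelengthGrid
    normalized: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.dtype not in (np.float32, np.float64):
            v = v.astype(np.float32)
        if v.ndim != 3:
            raise ValueError("hypercube values must be H×W×L")
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("hypercube spatial dimensions must be positive")
        if v.shape[2] != len(self.grid):
            raise ValueError(
                f"band count {v.shape[2]} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("hypercube values must be finite")
        if self.normalized not in ("raw", "snv"):
            raise ValueError("normalized must be 'raw' or 'snv'")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class AnnotationMask:
    """H×W categorical raster with codes in :data:`MASK_CODES`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int64)
        bad = set(np.unique(lab)) - set(MASK_CODES)
        if bad:
            raise FormatError(f"mask contains unknown class codes {sorted(bad)}")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def annotated(self) -> np.ndarray:
        """Boolean raster of annotated (non-zero) pixels."""
        return self.labels != 0


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    organ_group: str  # "colon" | "esophagogastric"
    cube_path: str
    mask_path: str
    age: int | None = None
    sex: str | None = None
    tissue_location: str = ""
    t_classification: str = ""
    grade: str = ""

    def __post_init__(self) -> None:
        if self.organ_group not in ("colon", "esophagogastric"):
            raise ValueError(f"unknown organ group {self.organ_group!r}")


@dataclass
class DatasetManifest:
    """Ordered patient records: one hypercube + mask per patient."""

    records: list[PatientRecord]
    name: str = "cohort"

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("manifest must contain at least one patient")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique within a manifest")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def patient(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(f"patient {patient_id!r} not in manifest")

    def group(self, organ_group: str) -> list[PatientRecord]:
        return [r for r in self.records if r.organ_group == organ_group]


# ---------------------------------------------------------------------------
# ENVI cube I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32}


def write_cube(cube: Hypercube, path: str | Path) -> Path:
    """Write ``cube`` as an ENVI header/raster pair.

    ``path`` may carry any suffix; the header is written to ``<stem>.hdr``
    and the band-sequential float32 raster to ``<stem>.raw``.  Returns the
    header path.
    """
    path = Path(path)
    stem = path.with_suffix("")
    hdr, raw = stem.with_suffix(".hdr"), stem.with_suffix(".raw")
    h, w, L = cube.shape
    wl = ", ".join(repr(x) for x in cube.grid.wavelengths_nm)
    header = (
        "ENVI\n"
        "description = {hsicad hypercube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {L}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"normalized = {cube.normalized}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr.write_text(header)
    # BSQ: band-major on disk
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4").tofile(raw)
    return hdr


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header")
    # join brace-delimited multi-line values, then split on key = value
    fields: dict[str, str] = {}
    for m in re.finditer(r"^([a-z ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)$", text, re.M | re.S):
        fields[m.group(1).strip()] = m.group(2).strip()
    return fields


def read_cube(path: str | Path) -> Hypercube:
    """Read an ENVI header/raster pair written by :func:`write_cube`."""
    path = Path(path)
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_envi_header(hdr.read_text())
    try:
        h = int(fields["lines"])
        w = int(fields["samples"])
        L = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as e:
        raise FormatError(f"ENVI header missing field {e}") from e
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing wavelength list")
    wl_text = fields["wavelength"].strip("{} \n")
    wavelengths = [float(x) for x in wl_text.replace("\n", " ").split(",") if x.strip()]
    if len(wavelengths) != L:
        raise FormatError(
            f"header declares {L} bands but lists {len(wavelengths)} wavelengths"
        )
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"unsupported interleave {interleave!r}")
    dtype = _ENVI_DTYPES.get(dtype_code)
    if dtype is None:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    raw = hdr.with_suffix(".raw")
    data = np.fromfile(raw, dtype="<f4")
    if data.size != h * w * L:
        raise FormatError(
            f"raster holds {data.size} values, header implies {h * w * L}"
        )
    values = np.moveaxis(data.reshape(L, h, w), 0, 2)
    return Hypercube(
        values=values,
        grid=WavelengthGrid(tuple(wavelengths)),
        normalized=fields.get("normalized", "raw"),
    )


# ---------------------------------------------------------------------------
# Mask I/O (indexed PNG)
# ---------------------------------------------------------------------------

def write_mask(mask: AnnotationMask, path: str | Path) -> Path:
    path = Path(path)
    img = Image.fromarray(mask.labels, mode="P")
    palette = [0] * 768
    for code, (r, g, b) in MASK_PALETTE.items():
        palette[3 * code : 3 * code + 3] = [r, g, b]
    img.putpalette(palette)
    img.save(path, format="PNG")
    return path


def read_mask(path: str | Path, expect_shape: tuple[int, int] | None = None) -> AnnotationMask:
    """Read an indexed PNG mask; validates codes and (optionally) shape."""
    img = Image.open(Path(path))
    if img.mode not in ("P", "L"):
        raise FormatError(f"mask image mode {img.mode!r} is not indexed/grayscale")
    labels = np.asarray(img, dtype=np.int64)
    if expect_shape is not None and labels.shape != tuple(expect_shape):
        raise FormatError(
            f"mask shape {labels.shape} does not match expected {tuple(expect_shape)}"
        )
    return AnnotationMask(labels=labels)  # code validation in __post_init__


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "patient_id",
    "organ_group",
    "cube_path",
    "mask_path",
    "age",
    "sex",
    "tissue_location",
    "t_classification",
    "grade",
]


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=_MANIFEST_COLUMNS)
        writer.writeheader()
        for r in manifest.records:
            writer.writerow(
                {
                    "patient_id": r.patient_id,
                    "organ_group": r.organ_group,
                    "cube_path": r.cube_path,
                    "mask_path": r.mask_path,
                    "age": "" if r.age is None else r.age,
                    "sex": r.sex or "",
                    "tissue_location": r.tissue_location,
                    "t_classification": r.t_classification,
                    "grade": r.grade,
                }
            )
    return path


def read_manifest(path: str | Path, name: str | None = None) -> DatasetManifest:
    path = Path(path)
    records = []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    organ_group=row["organ_group"],
                    cube_path=row["cube_path"],
                    mask_path=row["mask_path"],
                    age=int(row["age"]) if row.get("age") else None,
                    sex=row.get("sex") or None,
                    tissue_location=row.get("tissue_location", ""),
                    t_classification=row.get("t_classification", ""),
                    grade=row.get("grade", ""),
                )
            )
    return DatasetManifest(records=records, name=name or path.stem)


def load_patient(record: PatientRecord, root: str | Path | None = None) -> tuple[Hypercube, AnnotationMask]:
    """Load a patient's cube and mask, resolving relative paths against ``root``."""
    root = Path(root) if root is not None else Path(".")
    cube = read_cube(root / record.cube_path)
    mask = read_mask(root / record.mask_path, expect_shape=cube.shape[:2])
    return cube, mask


# ---------------------------------------------------------------------------
# Dataset statistics and label handling
# ---------------------------------------------------------------------------

def synthesize_rgb(cube: Hypercube) -> np.ndarray:
    """Simulate an RGB display image from the visible bands of a hypercube.

    R, G, B are the bands nearest 630, 532 and 465 nm, each independently
    rescaled to [0, 1] by its own min/max (a constant band maps to 0).
    """
    wl = cube.grid.as_array()
    if wl.min() > 700 or wl.max() < 465:
        raise ValueError("wavelength grid does not span the visible range")
    out = np.zeros(cube.shape[:2] + (3,), dtype=np.float64)
    for i, target in enumerate((630.0, 532.0, 465.0)):
        band = cube.values[:, :, cube.grid.nearest_band(target)].astype(np.float64)
        lo, hi = band.min(), band.max()
        if hi > lo:
            out[:, :, i] = (band - lo) / (hi - lo)
    return out


def class_proportions(
    manifest: DatasetManifest, root: str | Path | None = None
) -> "pd.DataFrame":
    """Per-patient and cohort-mean class percentages over annotated pixels.

    Returns a DataFrame indexed by patient id with one column per tissue
    class (percent of that patient's annotated pixels) plus a final
    ``"mean"`` row of unweighted per-patient means.
    """
    import pandas as pd

    class_codes = [c for c in MASK_CODES if c != 0]
    rows = {}
    for rec in manifest.records:
        mask = read_mask(Path(root or ".") / rec.mask_path)
        annotated = mask.annotated()
        n = int(annotated.sum())
        if n == 0:
            raise ValueError(f"patient {rec.patient_id} has zero annotated pixels")
        rows[rec.patient_id] = {
            MASK_CODES[c]: 100.0 * float((mask.labels == c).sum()) / n
            for c in class_codes
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["mean"] = df.mean(axis=0)
    return df


def binarize_labels(mask: AnnotationMask) -> np.ndarray:
    """Collapse tissue classes to the cancer-vs-healthy task.

    Healthy mucosa classes (colon, stomach, esophagus) become the negative
    class, cancer the positive class, unannotated pixels are ignored.
    Returns an H×W int8 raster with codes ``LABEL_IGNORE``/``LABEL_NEGATIVE``/
    ``LABEL_POSITIVE``.
    """
    out = np.full(mask.shape, LABEL_IGNORE, dtype=np.int8)
    out[np.isin(mask.labels, (1, 2, 3))] = LABEL_NEGATIVE
    out[mask.labels == 4] = LABEL_POSITIVE
    return out
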
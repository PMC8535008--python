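"""Published per-patient reference values of the clinical cohorts.

The clinical hypercubes themselves are not public, but the per-patient
leave-one-patient-out ROC-AUC values and the cohort composition tables of
the colon (12 patients, 2 cancer-free) and esophagogastric (10 patients)
studies are.  They are packaged here as plain CSV so that the aggregation
and statistical-comparison machinery can be exercised against published
numbers: recomputing the cohort mean ± sd rows and the paired-t-test
p-values from the per-patient cells.

Cells printed as "/" (patients without cancer tissue, for whom ROC-AUC is
undefined) load as NaN and are dropped by the accessors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reference_auc_table",
    "reference_auc_column",
    "reference_cohort_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("hsicad.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def reference_auc_table(which: str) -> pd.DataFrame:
    """Per-patient ROC-AUC table: ``"colon"``, ``"eg"`` or ``"cross"``.

    Colon/EG tables have model columns for within-group training plus
    ``*_combined`` columns for training on both cohorts; the cross table
    has a ``direction`` column (``eg_to_colon`` / ``colon_to_eg``).
    """
    if which not in ("colon", "eg", "cross"):
        raise ValueError(f"unknown table {which!r}")
    return _read(f"reference_auc_{which}.csv")


def reference_auc_column(which: str, column: str, direction: str | None = None) -> pd.Series:
    """One model's per-patient AUC values with undefined cells dropped."""
    df = reference_auc_table(which)
    if direction is not None:
        df = df[df["direction"] == direction]
    return df[column].dropna().reset_index(drop=True)


def reference_cohort_table(which: str) -> pd.DataFrame:
    """Cohort composition table (per-patient annotated-pixel percentages
    and clinical metadata): ``"colon"`` or ``"eg"``."""
    if which not in ("colon", "eg"):
        raise ValueError(f"unknown cohort {which!r}")
    return _read(f"reference_cohort_{which}.csv")
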
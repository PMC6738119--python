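"""Cohort table I/O: canonical schema, validation, round-trip serialisation.

Every analysis stage consumes a :class:`CohortTable`, a validated pandas
DataFrame with one row per patient. The on-disk format is delimited text
(comma by default, tab accepted) with one header row; missing values are
the empty string or ``NA``. A JSON sidecar (``<path>.meta.json``) carries
provenance metadata.

Canonical columns
-----------------
patient_id            opaque unique string
screen_dim_major/minor paired screening-mammogram lesion diameters, mm
diag_dim_major/minor  paired diagnostic-mammogram lesion diameters, mm
interval_days         days between the two mammograms (``interval_months``
                      accepted instead and converted at 30.44 days/month)
age_years             age at diagnosis
grade                 histological grade, ordinal 1-3
histological_size_mm  invasive tumour size on pathology, mm
npi                   Nottingham Prognostic Index; computed as
                      0.2 * size_cm + grade + nodal_stage when absent and
                      the components are present
mitotic_score         ordinal 1-3 (mitotic component of grading)
nodal_stage           lymph-node stage, ordinal 1-3
ki67_percent          percent Ki67-positive tumour cells, 0-100
er_status/pr_status/her2_status  positive / negative / missing
lvi                   lymphovascular invasion: negative / probable / definite
subtype               luminal A / luminal B / HER2 / TNBC / BLBC
bcss_months           breast cancer-specific survival time, months
event                 1 = death from breast cancer, 0 = censored

The reader enforces ``dim_major >= dim_minor`` by swapping (with a
warning); rows violating hard invariants (Ki67 outside [0, 100], grade
outside {1,2,3}, negative survival time, event outside {0,1}, a
non-positive dimension) are rejected with row-indexed diagnostics.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .growth import DAYS_PER_MONTH

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

NUMERIC_COLUMNS = (
    "screen_dim_major",
    "screen_dim_minor",
    "diag_dim_major",
    "diag_dim_minor",
    "interval_days",
    "age_years",
    "grade",
    "histological_size_mm",
    "npi",
    "mitotic_score",
    "nodal_stage",
    "ki67_percent",
    "bcss_months",
    "event",
)

TRISTATE_COLUMNS = ("er_status", "pr_status", "her2_status")
TRISTATE_VALUES = ("positive", "negative")
LVI_VALUES = ("negative", "probable", "definite")
SUBTYPE_VALUES = ("luminal A", "luminal B", "HER2", "TNBC", "BLBC")

CATEGORICAL_VALUES = {
    "er_status": TRISTATE_VALUES,
    "pr_status": TRISTATE_VALUES,
    "her2_status": TRISTATE_VALUES,
    "lvi": LVI_VALUES,
    "subtype": SUBTYPE_VALUES,
}

CANONICAL_COLUMNS = (
    "patient_id",
    *NUMERIC_COLUMNS[:5],
    "age_years",
    "grade",
    "histological_size_mm",
    "npi",
    "mitotic_score",
    "nodal_stage",
    "ki67_percent",
    "er_status",
    "pr_status",
    "her2_status",
    "lvi",
    "subtype",
    "bcss_months",
    "event",
)

#: columns that must appear in the header (interval may come as months)
MANDATORY_COLUMNS = (
    "patient_id",
    "screen_dim_major",
    "screen_dim_minor",
    "diag_dim_major",
    "diag_dim_minor",
    "bcss_months",
    "event",
)

MISSING_MARKERS = ("", "NA", "NaN", "nan")


@dataclass
class CohortTable:
    """A validated patient-level cohort.

    ``df`` holds one row per patient with the canonical columns;
    ``diagnostics`` collects row-indexed messages from validation.
    """

    df: pd.DataFrame
    provenance: str = ""
    schema_version: str = SCHEMA_VERSION
    diagnostics: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), self.provenance, self.schema_version, list(self.diagnostics))


def _coerce_numeric(df: pd.DataFrame, col: str) -> pd.Series:
    raw = df[col]
    coerced = pd.to_numeric(raw, errors="coerce")
    bad = raw.notna() & coerced.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {raw.iloc[row]!r} in column '{col}' at data row {row}",
            row=row,
            column=col,
        )
    return coerced.astype(float)


def read_cohort(path, delimiter: str | None = None, provenance: str | None = None) -> CohortTable:
    """Read and validate a delimited-text cohort table.

    Raises :class:`SchemaError` if a mandatory column is missing and
    :class:`ParseError` (with row index) on an unparsable numeric cell.
    Rows failing hard invariants are dropped with diagnostics recorded on
    the returned table; soft issues (swapped dimensions) are repaired with
    a warning.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        na_values=list(MISSING_MARKERS),
        keep_default_na=False,
        skipinitialspace=True,
    )
    df.columns = [c.strip().lower() for c in df.columns]
    diagnostics: list[str] = []

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing: {', '.join(missing)}")
    if "interval_days" not in df.columns and "interval_months" not in df.columns:
        raise SchemaError("mandatory column(s) missing: interval_days (or interval_months)")

    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series([np.nan] * len(df), dtype=object)

    numeric_present = [c for c in NUMERIC_COLUMNS if c in df.columns]
    for col in numeric_present:
        df[col] = _coerce_numeric(df, col)
    if "interval_months" in df.columns:
        months = _coerce_numeric(df, "interval_months")
        need = df["interval_days"].isna() & months.notna()
        df.loc[need, "interval_days"] = months[need] * DAYS_PER_MONTH
        df = df.drop(columns=["interval_months"])

    for col, allowed in CATEGORICAL_VALUES.items():
        vals = df[col].astype(object).where(df[col].notna(), np.nan)
        bad = vals.notna() & ~vals.isin(allowed)
        if bad.any():
            for row in np.flatnonzero(bad.to_numpy()):
                diagnostics.append(
                    f"row {row}: invalid value {vals.iloc[row]!r} in '{col}' set to missing"
                )
            vals.loc[bad] = np.nan
        df[col] = vals

    # enforce major >= minor on both dimension pairs
    n_swapped = 0
    for pre in ("screen", "diag"):
        hi, lo = f"{pre}_dim_major", f"{pre}_dim_minor"
        both = df[hi].notna() & df[lo].notna()
        swap = both & (df[hi] < df[lo])
        if swap.any():
            n_swapped += int(swap.sum())
            tmp = df.loc[swap, hi].copy()
            df.loc[swap, hi] = df.loc[swap, lo]
            df.loc[swap, lo] = tmp
    if n_swapped:
        msg = f"reordered {n_swapped} dimension pair(s) so that major >= minor"
        warnings.warn(msg, stacklevel=2)
        diagnostics.append(msg)

    # hard row invariants
    bad_rows = pd.Series(False, index=df.index)

    def _flag(mask: pd.Series, reason: str):
        nonlocal bad_rows
        for row in np.flatnonzero((mask & ~bad_rows).to_numpy()):
            diagnostics.append(f"row {row} rejected: {reason}")
        bad_rows |= mask

    for col in ("screen_dim_major", "screen_dim_minor", "diag_dim_major", "diag_dim_minor"):
        _flag(df[col].notna() & (df[col] <= 0), f"non-positive {col}")
    _flag(df["ki67_percent"].notna() & ~df["ki67_percent"].between(0, 100), "ki67 outside [0, 100]")
    for col in ("grade", "mitotic_score", "nodal_stage"):
        _flag(df[col].notna() & ~df[col].isin([1.0, 2.0, 3.0]), f"{col} outside {{1,2,3}}")
    _flag(df["bcss_months"].notna() & (df["bcss_months"] < 0), "negative bcss_months")
    _flag(df["event"].notna() & ~df["event"].isin([0.0, 1.0]), "event outside {0,1}")
    if bad_rows.any():
        df = df[~bad_rows].reset_index(drop=True)

    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient_id values: {dupes}")

    # NPI from components when absent: 0.2 * size_cm + grade + nodal_stage
    need_npi = (
        df["npi"].isna()
        & df["histological_size_mm"].notna()
        & df["grade"].notna()
        & df["nodal_stage"].notna()
    )
    if need_npi.any():
        df.loc[need_npi, "npi"] = (
            0.2 * df.loc[need_npi, "histological_size_mm"] / 10.0
            + df.loc[need_npi, "grade"]
            + df.loc[need_npi, "nodal_stage"]
        )

    meta_path = Path(str(path) + ".meta.json")
    prov = provenance
    schema_version = SCHEMA_VERSION
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        prov = prov if prov is not None else meta.get("provenance", "")
        schema_version = meta.get("schema_version", SCHEMA_VERSION)
    df = df[list(CANONICAL_COLUMNS)]
    for msg in diagnostics:
        log.info("%s: %s", path.name, msg)
    return CohortTable(df, provenance=prov or "", schema_version=schema_version, diagnostics=diagnostics)


def write_cohort(cohort: CohortTable, path, delimiter: str = ",") -> Path:
    """Write a cohort table (plus JSON provenance sidecar); returns the path.

    ``read_cohort(write_cohort(c))`` reproduces ``c`` field-for-field, and a
    second write of the re-read table is byte-identical to the first.
    """
    path = Path(path)
    df = cohort.df[list(CANONICAL_COLUMNS)].copy()
    df.to_csv(path, sep=delimiter, index=False, na_rep="")
    meta = {"provenance": cohort.provenance, "schema_version": cohort.schema_version}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True, indent=2) + "\n")
    return path


def complete_case_subset(cohort: CohortTable, required_fields) -> CohortTable:
    """Restrict to records non-missing on every required field.

    Mirrors the restriction of an analysis to cases with complete
    clinicopathological and outcome data. The number of dropped records is
    logged; an unknown field name raises ``KeyError``; an empty requirement
    is the identity. Idempotent.
    """
    required = list(required_fields)
    unknown = [f for f in required if f not in cohort.df.columns]
    if unknown:
        raise KeyError(f"unknown field(s): {', '.join(unknown)}")
    if not required:
        return cohort.copy()
    keep = cohort.df[required].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("complete_case_subset: dropped %d of %d records", dropped, len(cohort.df))
    if keep.sum() == 0:
        warnings.warn("complete_case_subset removed every record", stacklevel=2)
    out = cohort.df[keep].reset_index(drop=True)
    diag = list(cohort.diagnostics)
    if dropped:
        diag.append(f"complete_case_subset dropped {dropped} record(s) on {required}")
    return CohortTable(out, cohort.provenance, cohort.schema_version, diag)


def cohort_from_frame(df: pd.DataFrame, provenance: str = "") -> CohortTable:
    """Build a CohortTable from an in-memory frame, filling absent optional columns."""
    df = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return CohortTable(df[list(CANONICAL_COLUMNS)].reset_index(drop=True), provenance=provenance)
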
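"""Long-format regional uptake tables: schema, validation, round-trip I/O.

Every stage of the pipeline exchanges one tidy table layout::

    subject_id, genotype, arm, age_months, tracer, voi, value, unit

with one row per (subject, tracer, age, VOI) measurement.  ``unit`` is
homogeneous within a table and one of ``PCT_ID`` (percent injected dose per
cc), ``SUVR`` (ratio to a pseudo-reference region) or ``ZSCORE``
(control-referenced z-score).  Uptake in PCT_ID/SUVR units must be strictly
positive; z-scores may take any sign.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "COLUMNS",
    "UNITS",
    "GENOTYPES",
    "TREATMENTS",
    "TableError",
    "validate_table",
    "read_table",
    "write_table",
]

COLUMNS = ("subject_id", "genotype", "arm", "age_months", "tracer", "voi", "value", "unit")
KEY = ("subject_id", "tracer", "age_months", "voi")
UNITS = ("PCT_ID", "SUVR", "ZSCORE")
GENOTYPES = ("WT", "KI")
TREATMENTS = ("PL/PL", "Ab/PL", "PL/Pio", "Ab/Pio")
TRACERS = ("TSPO", "ABETA")


class TableError(ValueError):
    """Raised when a table violates the uptake-table schema.

    Carries per-row diagnostics in ``.diagnostics`` (list of strings).
    """

    def __init__(self, message: str, diagnostics: list[str] | None = None):
        self.diagnostics = diagnostics or []
        if self.diagnostics:
            message = message + "\n  " + "\n  ".join(self.diagnostics[:20])
            if len(self.diagnostics) > 20:
                message += f"\n  ... and {len(self.diagnostics) - 20} more"
        super().__init__(message)


def validate_table(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Schema-check an uptake table (path or DataFrame) and return it typed.

    Rejects missing columns, unknown units/genotypes/treatments, mixed units,
    non-positive PCT_ID/SUVR values, non-finite values, and duplicate
    (subject, tracer, age, voi) keys — each with row-level diagnostics.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = table.copy()

    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"missing required columns: {missing}")
    df = df.loc[:, list(COLUMNS)]
    df["age_months"] = pd.to_numeric(df["age_months"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    diags: list[str] = []
    for idx, row in df[df["age_months"].isna() | df["value"].isna()].iterrows():
        diags.append(f"row {idx}: non-numeric age_months or value")
    bad_unit = ~df["unit"].isin(UNITS)
    for idx in df.index[bad_unit]:
        diags.append(f"row {idx}: unknown unit {df.at[idx, 'unit']!r}")
    units_present = df.loc[~bad_unit, "unit"].unique()
    if len(units_present) > 1:
        raise TableError(
            f"unit column mixes {sorted(units_present)}; tables are unit-homogeneous"
        )
    bad_gt = ~df["genotype"].isin(GENOTYPES)
    for idx in df.index[bad_gt]:
        diags.append(f"row {idx}: unknown genotype {df.at[idx, 'genotype']!r}")
    bad_arm = ~df["arm"].isin(TREATMENTS)
    for idx in df.index[bad_arm]:
        diags.append(f"row {idx}: unknown treatment arm {df.at[idx, 'arm']!r}")
    bad_tracer = ~df["tracer"].isin(TRACERS)
    for idx in df.index[bad_tracer]:
        diags.append(f"row {idx}: unknown tracer {df.at[idx, 'tracer']!r}")
    if len(units_present) == 1 and units_present[0] in ("PCT_ID", "SUVR"):
        nonpos = df["value"].notna() & (df["value"] <= 0)
        for idx in df.index[nonpos]:
            diags.append(
                f"row {idx}: non-positive {units_present[0]} value {df.at[idx, 'value']}"
            )
    if diags:
        raise TableError("malformed rows", diags)

    dup = df.duplicated(subset=list(KEY), keep=False)
    if dup.any():
        keys = df.loc[dup, list(KEY)].drop_duplicates()
        diags = [
            "duplicate key (subject_id={}, tracer={}, age_months={}, voi={})".format(
                *rec
            )
            for rec in keys.itertuples(index=False)
        ]
        raise TableError("duplicate (subject, tracer, age, voi) keys", diags)
    return df.reset_index(drop=True)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an uptake CSV."""
    return validate_table(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an uptake table as CSV in canonical column and row order.

    Sorting plus a fixed float representation makes write -> read -> write
    byte-stable, which the pipeline manifest relies on.
    """
    out = df.loc[:, list(COLUMNS)].sort_values(list(KEY), kind="mergesort")
    out.to_csv(path, index=False, float_format="%.10g")


def to_wide(df: pd.DataFrame, tracer: str, age_months: float | None = None,
            vois: Iterable[str] | None = None) -> pd.DataFrame:
    """Pivot one tracer (optionally one timepoint) to a subject x VOI matrix.

    Subjects with any missing VOI are kept as NaN rows; callers decide on
    listwise deletion.
    """
    sel = df[df["tracer"] == tracer]
    if age_months is not None:
        sel = sel[sel["age_months"] == age_months]
    wide = sel.pivot_table(index="subject_id", columns="voi", values="value",
                           aggfunc="first")
    if vois is not None:
        wide = wide.reindex(columns=list(vois))
    return wide
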
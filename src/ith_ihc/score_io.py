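"""Reading, validating and writing focus-level score tables.

Canonical on-disk form is a long CSV with one row per
(tumor, focus, marker) cell::

    tumor_id,stage,focus_id,marker,score,fraction_positive
    T1,I,F1,PBRM1,2,
    T1,I,F1,ARID1A,0,

Wide per-marker layouts and spreadsheet score tables (one row per
tumor/focus with marker columns) are converted to this form on read.
Missing score cells become non-evaluable, never zero.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd

from .cohort import (
    Cohort,
    CohortValidationError,
    DEFAULT_MARKERS,
    FocusRecord,
    LONG_COLUMNS,
    cohort_from_records,
    stage_to_ordinal,
)

DIALECTS = ("long-csv", "wide-csv", "s1-xls")

#: Permissive header aliases for spreadsheet-style tables.
_HEADER_ALIASES = {
    "tumor_id": {"tumor_id", "tumor", "case", "case_id", "patient", "patient_id", "id"},
    "stage": {"stage", "tumor_stage", "pstage"},
    "focus_id": {"focus_id", "focus", "core", "core_id", "region", "spot"},
    "marker": {"marker", "protein", "antibody", "gene"},
    "score": {"score", "ihc_score", "value"},
    "fraction_positive": {
        "fraction_positive", "fraction", "percent_positive", "pct_positive",
    },
}


def _canon(col: str) -> str:
    key = str(col).strip().lower().replace(" ", "_").replace("-", "_")
    for canonical, aliases in _HEADER_ALIASES.items():
        if key in aliases:
            return canonical
    return str(col).strip()  # unmatched columns (e.g. marker names) kept as-is


class RowReport:
    """Per-row accept/reject accounting so validation is total."""

    def __init__(self) -> None:
        self.accepted = 0
        self.rejected: list[dict] = []

    def reject(self, row_index: int, reason: str) -> None:
        self.rejected.append({"row": row_index, "reason": reason})

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _records_from_long(
    df: pd.DataFrame, markers: tuple[str, ...], report: RowReport
) -> list[FocusRecord]:
    records = []
    for idx, row in df.iterrows():
        marker = str(row["marker"]).strip()
        if marker not in markers:
            report.reject(int(idx), f"unknown marker {marker!r}")
            continue
        score = row.get("score")
        frac = row.get("fraction_positive")
        score = None if pd.isna(score) else int(score)
        frac = None if pd.isna(frac) else float(frac)
        if score is not None and score not in (0, 1, 2):
            raise CohortValidationError(
                f"row {idx}: score {score!r} outside {{0,1,2}}"
            )
        evaluable = score is not None or frac is not None
        records.append(
            FocusRecord(
                tumor_id=str(row["tumor_id"]).strip(),
                stage=stage_to_ordinal(row["stage"]),
                focus_id=str(row["focus_id"]).strip(),
                marker=marker,
                fraction_positive=frac,
                score=score,
                evaluable=evaluable,
            )
        )
        report.accepted += 1
    return records


def _long_from_wide(df: pd.DataFrame, markers: tuple[str, ...]) -> pd.DataFrame:
    """Melt a per-focus wide table (one column per marker) to long form."""
    id_cols = [c for c in ("tumor_id", "stage", "focus_id") if c in df.columns]
    missing = {"tumor_id", "stage", "focus_id"} - set(id_cols)
    if missing:
        raise CohortValidationError(f"wide table lacks columns {sorted(missing)}")
    marker_cols = [c for c in df.columns if c in markers]
    extra = [c for c in df.columns if c not in id_cols and c not in marker_cols]
    if extra:
        warnings.warn(f"ignoring non-marker columns {extra}")
    long = df.melt(
        id_vars=id_cols, value_vars=marker_cols,
        var_name="marker", value_name="score",
    )
    long["fraction_positive"] = pd.NA
    return long


def read_cohort(
    path: str | Path,
    dialect: str = "long-csv",
    markers: tuple[str, ...] = DEFAULT_MARKERS,
    thresholds: tuple[float, float] = (0.05, 0.50),
) -> tuple[Cohort, RowReport]:
    """Read and validate a focus-level score table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``long-csv`` (canonical), ``wide-csv`` (marker columns), or
        ``s1-xls`` (spreadsheet with a permissive header map; wide or
        long orientation is auto-detected).
    markers
        Accepted marker registry; rows with other markers are rejected
        into the row report, not silently dropped.

    Returns
    -------
    (Cohort, RowReport)
        The validated cohort and a per-row accounting: accepted +
        rejected equals the number of input rows.

    Raises
    ------
    CohortValidationError
        On duplicate (tumor, focus, marker) keys, out-of-range scores,
        or an empty file.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "s1-xls":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise CohortValidationError("no records")
    df = df.rename(columns=_canon)
    is_wide = "marker" not in df.columns
    if dialect == "wide-csv" or (dialect == "s1-xls" and is_wide):
        df = _long_from_wide(df, markers)
    df = df.reset_index(drop=True)
    report = RowReport()
    records = _records_from_long(df, markers, report)
    if not records:
        raise CohortValidationError("no records")
    cohort = cohort_from_records(
        records, markers=markers, provenance=str(path), thresholds=thresholds
    )
    for t in cohort:
        if t.n_foci < 2:
            warnings.warn(
                f"tumor {t.tumor_id!r} has {t.n_foci} focus; "
                "retained but single-region trees are uninformative"
            )
    return cohort, report


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as canonical long CSV."""
    cohort.to_frame().to_csv(path, index=False)


def write_results(tables: dict, out_dir: str | Path) -> dict:
    """Write result tables with deterministic names; return a manifest.

    ``tables`` maps a name to a payload: DataFrames become
    ``<name>.csv`` (fixed column order as given), dicts become
    ``<name>.json``, and strings ending in ';' are treated as Newick and
    written to ``<name>.nwk``.  The manifest (also written as
    ``manifest.json``) lists every file with its row count.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        payload = tables[name]
        if isinstance(payload, pd.DataFrame):
            fn = f"{name}.csv"
            payload.to_csv(out / fn, index=False)
            n_rows = len(payload)
        elif isinstance(payload, str) and payload.rstrip().endswith(";"):
            fn = f"{name}.nwk"
            (out / fn).write_text(payload.rstrip() + "\n")
            n_rows = 1
        elif isinstance(payload, (dict, list)):
            fn = f"{name}.json"
            (out / fn).write_text(json.dumps(payload, indent=2, default=str) + "\n")
            n_rows = len(payload)
        else:
            raise TypeError(f"unsupported table type for {name!r}: {type(payload)}")
        entries.append({"name": name, "file": fn, "rows": n_rows})
    manifest = {"n_files": len(entries), "files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
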
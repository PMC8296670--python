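"""Reading and writing patient tables and report files.

Patient tables are delimited text (comma by default, tab accepted) with
a mandatory header row, UTF-8, missing values as empty cells.  Unknown
columns are ignored.  Row-level validation failures are reported with
1-based data row numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import PatientRecord, RecordValidationError

__all__ = [
    "read_patient_table",
    "write_patient_table",
    "records_to_frame",
    "frame_to_records",
    "write_report_tables",
]

MANDATORY_COLUMNS = (
    "patient_id",
    "cohort_id",
    "sex",
    "age",
    "kl_grade",
    "bmi",
    "strength_instrument",
    "strength_baseline",
    "pain_baseline_raw",
    "pain_scale",
    "womac_pf_baseline",
    "exercise_arm",
)
OPTIONAL_COLUMNS = (
    "knee_surgery",
    "comorbidity_count",
    "pain_fu_raw",
    "womac_pf_fu",
    "strength_fu",
)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value, column: str):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise RecordValidationError(f"column {column!r}: cannot parse boolean {value!r}")


def _opt_float(value):
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def _opt_int(value):
    v = _opt_float(value)
    return None if v is None else int(v)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Validate a DataFrame row-wise into :class:`PatientRecord` objects."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing mandatory column(s): {missing}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    cohort_id=str(row["cohort_id"]),
                    sex=str(row["sex"]).strip().lower(),
                    age=float(row["age"]),
                    kl_grade=int(row["kl_grade"]),
                    bmi=float(row["bmi"]),
                    strength_instrument=str(row["strength_instrument"]),
                    strength_baseline=float(row["strength_baseline"]),
                    pain_baseline_raw=float(row["pain_baseline_raw"]),
                    pain_scale=str(row["pain_scale"]),
                    womac_pf_baseline=float(row["womac_pf_baseline"]),
                    exercise_arm=bool(_parse_bool(row["exercise_arm"], "exercise_arm")),
                    knee_surgery=_parse_bool(row.get("knee_surgery"), "knee_surgery"),
                    comorbidity_count=_opt_int(row.get("comorbidity_count")),
                    pain_fu_raw=_opt_float(row.get("pain_fu_raw")),
                    womac_pf_fu=_opt_float(row.get("womac_pf_fu")),
                    strength_fu=_opt_float(row.get("strength_fu")),
                )
            )
        except (RecordValidationError, ValueError) as exc:
            raise RecordValidationError(f"row {pos}: {exc}") from exc
    return records


def read_patient_table(path: str | Path, dialect: str = "comma") -> list[PatientRecord]:
    """Read and validate a delimited patient table.

    ``dialect`` is ``"comma"`` or ``"tab"``.  Every row becomes a
    validated record; the first invalid row aborts with an error naming
    the row.
    """
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (use 'comma' or 'tab')")
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str}, keep_default_na=True)
    return frame_to_records(df)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Serialize records to a DataFrame with the canonical columns."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "cohort_id": r.cohort_id,
                "sex": r.sex.value,
                "age": r.age,
                "kl_grade": r.kl_grade,
                "bmi": r.bmi,
                "strength_instrument": r.strength_instrument,
                "strength_baseline": r.strength_baseline,
                "pain_baseline_raw": r.pain_baseline_raw,
                "pain_scale": r.pain_scale.value,
                "womac_pf_baseline": r.womac_pf_baseline,
                "exercise_arm": r.exercise_arm,
                "knee_surgery": r.knee_surgery,
                "comorbidity_count": r.comorbidity_count,
                "pain_fu_raw": r.pain_fu_raw,
                "womac_pf_fu": r.womac_pf_fu,
                "strength_fu": r.strength_fu,
            }
        )
    return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_patient_table(
    records: Iterable[PatientRecord], path: str | Path, dialect: str = "comma"
) -> None:
    sep = {"comma": ",", "tab": "\t"}[dialect]
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def write_report_tables(results: dict, outdir: str | Path) -> list[Path]:
    """Write the report bundle as delimited files.

    ``results`` maps report names to DataFrames (or objects exposing
    ``to_frame``), typically: ``proportions``, ``effects``,
    ``verdicts``, ``aggregate``.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in results.items():
        df = obj.to_frame() if hasattr(obj, "to_frame") else obj
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
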
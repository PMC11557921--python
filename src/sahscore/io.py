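"""Typed patient-table I/O and per-patient score application.

The interchange format is RFC-4180 CSV (UTF-8, "." decimal), one row per
patient, with an explicit empty cell meaning missing. The column dictionary
below is the single source of truth: readers reject unknown or missing
columns by name, and every scoring stage appends columns without touching
the input ones.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .comorbidity import CHARLSON_WEIGHTS, ComorbidityFlags, charlson_index
from .ebi import BloodBurdenInputs, assess_ebi
from .lods import OrganObservations, compute_lods

logger = logging.getLogger("sahscore")

__all__ = [
    "PATIENT_COLUMNS",
    "read_patient_table",
    "write_table",
    "score_lods_table",
    "score_ebi_table",
    "score_cci_table",
]

OBSERVATION_COLUMNS = [
    "gcs_min", "hr_min", "hr_max", "sbp_min", "sbp_max", "urea_max",
    "creatinine_max", "urine_24h", "ventilated_or_cpap", "pao2_fio2",
    "pao2_fio2_unit", "wbc_min", "wbc_max", "platelets_min",
    "bilirubin_max", "pt_excess_sec",
]
CISTERN_COLUMNS = [f"cistern_g{i}" for i in range(1, 11)]
VENTRICLE_COLUMNS = [f"ventricle_g{i}" for i in range(1, 5)]
EBI_INPUT_COLUMNS = (
    CISTERN_COLUMNS + VENTRICLE_COLUMNS
    + ["hematoma_a_cm", "hematoma_b_cm", "hematoma_c_cm", "loc", "edema"]
)
COMORBIDITY_COLUMNS = list(CHARLSON_WEIGHTS)
OUTCOME_COLUMNS = ["age", "treatment", "mrs", "died_in_hospital"]

#: Full patient-CSV column dictionary, in canonical order.
PATIENT_COLUMNS = (
    ["patient_id"] + OBSERVATION_COLUMNS + EBI_INPUT_COLUMNS
    + COMORBIDITY_COLUMNS + OUTCOME_COLUMNS
)

_BOOL_COLUMNS = {"ventilated_or_cpap", "loc", "edema",
                 "died_in_hospital", *COMORBIDITY_COLUMNS}


class TableFormatError(ValueError):
    """Malformed patient table (bad header or unparsable cells)."""


class RowValidationError(ValueError):
    """A patient row failed validation; carries the offending row numbers."""


def _coerce_bool(col: pd.Series) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "": None, "nan": None}
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        s = str(v).strip().lower()
        if s not in mapping:
            raise TableFormatError(f"cannot parse boolean value {v!r} in '{col.name}'")
        return mapping[s]
    return col.map(conv)


def read_patient_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a patient CSV against the column dictionary.

    Unknown columns, and missing required columns, are hard errors naming
    the column. Boolean columns accept true/false/1/0 and blank-for-missing.
    """
    frame = pd.read_csv(path, dtype={"patient_id": str, "treatment": str,
                                     "pao2_fio2_unit": str})
    unknown = [c for c in frame.columns if c not in PATIENT_COLUMNS]
    if unknown:
        raise TableFormatError(f"unknown column(s): {', '.join(unknown)}")
    missing = [c for c in PATIENT_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
    frame = frame[PATIENT_COLUMNS]
    for c in _BOOL_COLUMNS:
        frame[c] = _coerce_bool(frame[c])
    frame["pao2_fio2_unit"] = frame["pao2_fio2_unit"].fillna("mmHg")
    return frame


def write_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a table as deterministic CSV (fixed float format, no index)."""
    out = frame.copy()
    for c in out.columns:
        if c in _BOOL_COLUMNS and out[c].notna().all():
            out[c] = out[c].astype(bool)
    out.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def _row_value(row: pd.Series, col: str):
    v = row[col]
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def _observations_from_row(row: pd.Series) -> OrganObservations:
    fields = {c: _row_value(row, c) for c in OBSERVATION_COLUMNS}
    if fields["gcs_min"] is not None:
        fields["gcs_min"] = int(fields["gcs_min"])
    fields["pao2_fio2_unit"] = fields["pao2_fio2_unit"] or "mmHg"
    return OrganObservations(**fields)


def score_lods_table(frame: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Append LODS breakdown columns (``lods_*``) to a patient table.

    With ``strict`` false, rows that fail validation get empty score cells
    and a log entry instead of aborting the run.
    """
    records, bad_rows = [], []
    for idx, row in frame.iterrows():
        try:
            b = compute_lods(_observations_from_row(row))
            records.append({
                "lods_neurologic": b.neurologic,
                "lods_cardiovascular": b.cardiovascular,
                "lods_renal": b.renal,
                "lods_pulmonary": b.pulmonary,
                "lods_hematologic": b.hematologic,
                "lods_hepatic": b.hepatic,
                "lods_total": b.total,
                "lods_total_without_gcs": b.total_without_gcs,
                "lods_missing_fields": ";".join(b.missing_fields),
            })
            if b.missing_fields:
                logger.debug("row %s: missing fields scored as normal: %s",
                             idx, b.missing_fields)
        except (ValueError, TypeError) as exc:
            if strict:
                raise RowValidationError(f"row {idx}: {exc}") from exc
            logger.warning("row %s skipped in LODS scoring: %s", idx, exc)
            bad_rows.append(idx)
            records.append({})
    return pd.concat([frame.reset_index(drop=True),
                      pd.DataFrame(records)], axis=1)


def score_ebi_table(frame: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Append EBI assessment columns (``ebi_*``) to a patient table."""
    records = []
    for idx, row in frame.iterrows():
        try:
            diam = tuple(_row_value(row, c) for c in
                         ("hematoma_a_cm", "hematoma_b_cm", "hematoma_c_cm"))
            diam = None if any(v is None for v in diam) else diam
            inputs = BloodBurdenInputs(
                cistern_grades=[int(row[c]) for c in CISTERN_COLUMNS],
                ventricle_grades=[int(row[c]) for c in VENTRICLE_COLUMNS],
                hematoma_diameters=diam,
            )
            a = assess_ebi(inputs, loc=bool(row["loc"]), edema=bool(row["edema"]))
            records.append({
                "ebi_hijdra": a.hijdra,
                "ebi_leroux": a.leroux,
                "ebi_ich_volume_ml": a.ich_volume_ml,
                "ebi_ich_points": a.ich_points,
                "ebi_burden_total": a.burden_total,
                "ebi_burden_points": a.burden_points,
                "ebi_grade": a.grade,
                "severe_ebi": a.severe,
            })
        except (ValueError, TypeError) as exc:
            if strict:
                raise RowValidationError(f"row {idx}: {exc}") from exc
            logger.warning("row %s skipped in EBI scoring: %s", idx, exc)
            records.append({})
    return pd.concat([frame.reset_index(drop=True),
                      pd.DataFrame(records)], axis=1)


def score_cci_table(frame: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Append the Charlson Comorbidity Index column (``cci``)."""
    values = []
    for idx, row in frame.iterrows():
        try:
            flags = ComorbidityFlags(
                **{c: bool(row[c]) if row[c] is not None else False
                   for c in COMORBIDITY_COLUMNS}
            )
            values.append(charlson_index(flags))
        except ValueError as exc:
            if strict:
                raise RowValidationError(f"row {idx}: {exc}") from exc
            logger.warning("row %s skipped in CCI scoring: %s", idx, exc)
            values.append(None)
    out = frame.reset_index(drop=True).copy()
    out["cci"] = values
    return out
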
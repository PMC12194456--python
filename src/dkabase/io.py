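"""CSV interchange for cohorts, panels and fluid administrations.

All data interchange is plain CSV: UTF-8, "." decimal separator, missing
values as empty cells.  Column names are documented in ``docs/SCHEMAS.md``.
Two panel layouts exist:

* a *long* panel file, one row per patient-timepoint;
* a *wide* cohort file, one row per patient, combining demographics and
  outcomes with the panel columns suffixed ``_adm`` / ``_h6`` / ``_h24``.

Readers validate the header and every cell, reporting schema violations with
row and column; writers emit shortest-round-trip float representations so a
write/read cycle is lossless.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .acid_base import TimepointPanel
from .cohort import ADMISSION, H6, H24, PatientRecord
from .errors import SchemaError
from .fluids import FluidAdministration

__all__ = [
    "read_cohort_csv", "write_cohort_csv",
    "read_panels_csv", "write_panels_csv",
    "read_admins_csv", "write_admins_csv",
    "PANEL_CSV_FIELDS", "DEMOGRAPHIC_CSV_FIELDS",
]

#: panel attribute -> CSV base column name (units encoded in the name)
PANEL_CSV_FIELDS: Tuple[Tuple[str, str], ...] = (
    ("ph", "ph"),
    ("paco2", "paco2_mmhg"),
    ("hco3_measured", "hco3_mmol_l"),
    ("sbe_measured", "sbe_mmol_l"),
    ("na", "na_mmol_l"),
    ("k", "k_mmol_l"),
    ("ca", "ca_meq_l"),
    ("mg", "mg_meq_l"),
    ("cl", "cl_mmol_l"),
    ("lactate", "lactate_mmol_l"),
    ("albumin", "albumin_g_l"),
    ("phosphate", "phosphate_mmol_l"),
    ("glucose", "glucose_mg_dl"),
    ("hematocrit", "hct_pct"),
    ("urine_ketones", "urine_ketones"),
    ("urea", "urea_mg_dl"),
    ("creatinine", "creatinine_mg_dl"),
)

#: record attribute -> CSV column name for the wide cohort file
DEMOGRAPHIC_CSV_FIELDS: Tuple[Tuple[str, str], ...] = (
    ("age_years", "age_years"),
    ("sex", "sex"),
    ("bmi_kg_m2", "bmi_kg_m2"),
    ("weight_kg", "weight_kg"),
    ("cci", "cci"),
    ("apache2", "apache2"),
    ("sofa", "sofa"),
    ("nahco3_bolus_mmol", "nahco3_bolus_mmol"),
    ("kcl_mmol", "kcl_mmol"),
    ("insulin_u_per_kg_h", "insulin_u_per_kg_h"),
    ("urine_output_ml_kg_h", "urine_output_ml_kg_h"),
    ("los_icu_days", "los_icu_days"),
)

_INT_FIELDS = {"urine_ketones", "cci", "apache2", "sofa"}
_STR_FIELDS = {"sex"}
_TP_SUFFIX = ((ADMISSION, "adm"), (H6, "h6"), (H24, "h24"))
TIMEPOINTS = ("admission", "h6", "h24")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        # keep integral floats compact but round-trippable
        return repr(value)
    return repr(value) if isinstance(value, float) else str(value)


def _parse(text: str, column: str, row: int, kind: str = "float"):
    if text == "" or text is None:
        return None
    try:
        if kind == "int":
            return int(float(text)) if float(text) == int(float(text)) \
                else (_ for _ in ()).throw(ValueError("not an integer"))
        if kind == "str":
            return text
        return float(text)
    except ValueError as exc:
        raise SchemaError(
            f"row {row}, column {column!r}: cannot parse {text!r} as {kind}"
        ) from exc


def _check_header(fieldnames, required, path):
    missing = [c for c in required if c not in (fieldnames or ())]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# --------------------------------------------------------------------------
# wide cohort CSV


def _cohort_columns() -> List[str]:
    cols = ["patient_id"] + [c for _, c in DEMOGRAPHIC_CSV_FIELDS]
    for _, suffix in _TP_SUFFIX:
        cols += [f"{c}_{suffix}" for _, c in PANEL_CSV_FIELDS]
    return cols


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    cols = _cohort_columns()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for rec in records:
            row = [rec.patient_id]
            row += [_fmt(getattr(rec, attr)) for attr, _ in DEMOGRAPHIC_CSV_FIELDS]
            for tp, _suffix in _TP_SUFFIX:
                panel = rec.panels.get(tp)
                for attr, _col in PANEL_CSV_FIELDS:
                    row.append(_fmt(getattr(panel, attr)) if panel else "")
            writer.writerow(row)


def read_cohort_csv(path) -> List[PatientRecord]:
    cols = _cohort_columns()
    records: List[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, cols, path)
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            if not pid:
                raise SchemaError(f"{path} row {i}: empty patient_id")
            kwargs = {}
            for attr, col in DEMOGRAPHIC_CSV_FIELDS:
                kind = "int" if attr in _INT_FIELDS else \
                    "str" if attr in _STR_FIELDS else "float"
                kwargs[attr] = _parse(row[col], col, i, kind)
            if kwargs.get("age_years") is None:
                raise SchemaError(f"{path} row {i}: age_years is required")
            if kwargs.get("sex") is None:
                kwargs["sex"] = "unknown"
            for numeric_default in ("nahco3_bolus_mmol", "kcl_mmol"):
                if kwargs.get(numeric_default) is None:
                    kwargs[numeric_default] = 0.0
            panels: Dict[str, TimepointPanel] = {}
            for tp, suffix in _TP_SUFFIX:
                values = {}
                any_present = False
                for attr, col in PANEL_CSV_FIELDS:
                    kind = "int" if attr in _INT_FIELDS else "float"
                    v = _parse(row[f"{col}_{suffix}"], f"{col}_{suffix}", i, kind)
                    values[attr] = v
                    any_present = any_present or v is not None
                if any_present:
                    panels[tp] = TimepointPanel(**values).validate()
            records.append(PatientRecord(patient_id=pid, panels=panels, **kwargs))
    return records


# --------------------------------------------------------------------------
# long panel CSV (one row per patient-timepoint)


def write_panels_csv(rows: Sequence[Tuple[str, str, TimepointPanel]], path) -> None:
    """``rows`` is a sequence of (patient_id, timepoint, panel)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "timepoint"] + [c for _, c in PANEL_CSV_FIELDS])
        for pid, tp, panel in rows:
            writer.writerow([pid, tp]
                            + [_fmt(getattr(panel, attr)) for attr, _ in PANEL_CSV_FIELDS])


def read_panels_csv(path) -> List[Tuple[str, str, TimepointPanel]]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames,
                      ["patient_id", "timepoint"] + [c for _, c in PANEL_CSV_FIELDS],
                      path)
        for i, row in enumerate(reader, start=2):
            tp = row["timepoint"]
            if tp not in TIMEPOINTS:
                raise SchemaError(
                    f"{path} row {i}: timepoint must be one of {TIMEPOINTS}, got {tp!r}")
            values = {
                attr: _parse(row[col], col, i,
                             "int" if attr in _INT_FIELDS else "float")
                for attr, col in PANEL_CSV_FIELDS
            }
            out.append((row["patient_id"], tp, TimepointPanel(**values).validate()))
    return out


# --------------------------------------------------------------------------
# administrations CSV


def write_admins_csv(admins: Sequence[FluidAdministration], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "fluid_name", "volume_ml", "window"])
        for a in admins:
            writer.writerow([a.patient_id, a.fluid_name, _fmt(a.volume_ml), a.window])


def read_admins_csv(path) -> List[FluidAdministration]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames,
                      ["patient_id", "fluid_name", "volume_ml", "window"], path)
        for i, row in enumerate(reader, start=2):
            v = _parse(row["volume_ml"], "volume_ml", i)
            if v is None:
                raise SchemaError(f"{path} row {i}: volume_ml is required")
            window = row["window"] or "first_6h"
            if window not in ("first_6h", "later"):
                raise SchemaError(
                    f"{path} row {i}, column 'window': got {window!r}")
            out.append(FluidAdministration(
                patient_id=row["patient_id"], fluid_name=row["fluid_name"],
                volume_ml=v, window=window))
    return out
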
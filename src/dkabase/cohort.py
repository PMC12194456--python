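"""Patient records, inclusion filtering and derived cohort columns.

A :class:`PatientRecord` bundles demographics, severity scores, blood-gas
panels at admission / 6 h / 24 h, the fluid administration list and the ICU
length of stay.  :func:`build_table` flattens a list of records into a pandas
DataFrame with the derived quantities the analysis runs on: strong ion gap
and base-excess chloride at admission and 6 h, the 6-hour deltas
(6th-hour value minus admission value), fluid loads, and the regimen-derived
group label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import acid_base as ab
from .acid_base import AcidBaseConstants, DEFAULT_CONSTANTS, TimepointPanel
from .errors import DomainError, MissingDataError
from .fluids import (
    FluidAdministration,
    FluidRegistry,
    classify_regimen,
    electrolyte_load,
)

__all__ = [
    "PatientRecord",
    "CohortTable",
    "apply_inclusion_filters",
    "compute_deltas",
    "incidence_per_1000",
    "group_counts",
    "build_table",
    "DELTA_VARIABLES",
    "REQUIRED_PANEL_FIELDS",
]

ADMISSION = "admission"
H6 = "h6"
H24 = "h24"

#: Panel fields that must be present at admission and 6 h for a record to be
#: analysable (SIG, BE_Cl and the delta battery all draw on these).  24-hour
#: urea/creatinine/ketones are carried but optional.
REQUIRED_PANEL_FIELDS = (
    "ph", "paco2", "na", "k", "ca", "mg", "cl", "lactate",
    "albumin", "phosphate", "glucose",
)

#: Variables differenced between admission and the 6th hour.
DELTA_VARIABLES = ("ph", "paco2", "hco3", "na", "cl", "sig", "lactate", "glucose", "becl")


@dataclass
class PatientRecord:
    patient_id: str
    age_years: float
    sex: str  # "male" / "female"
    bmi_kg_m2: Optional[float] = None
    weight_kg: Optional[float] = None
    cci: Optional[int] = None
    apache2: Optional[int] = None
    sofa: Optional[int] = None
    panels: Dict[str, TimepointPanel] = field(default_factory=dict)
    administrations: List[FluidAdministration] = field(default_factory=list)
    nahco3_bolus_mmol: float = 0.0
    kcl_mmol: float = 0.0
    insulin_u_per_kg_h: Optional[float] = None
    urine_output_ml_kg_h: Optional[float] = None
    los_icu_days: Optional[float] = None


@dataclass
class CohortTable:
    """Records plus the derived analysis DataFrame (one row per patient)."""

    records: List[PatientRecord]
    df: pd.DataFrame


def _panel_missing_fields(panel: TimepointPanel, fields: Sequence[str]) -> List[str]:
    return [f for f in fields if getattr(panel, f) is None]


def apply_inclusion_filters(
    records: Sequence[PatientRecord],
) -> Tuple[List[PatientRecord], List[Tuple[str, str]]]:
    """Apply the study inclusion rules.

    Kept records have age strictly above 18 years, a DKA-positive admission
    panel (glucose > 200 mg/dL, HCO3 < 15, pH < 7.3, ketones >= 2+) and no
    missing required field at admission or 6 h.  Everything else is logged
    with a reason, never raised.
    """
    included: List[PatientRecord] = []
    log: List[Tuple[str, str]] = []
    for rec in records:
        if rec.age_years <= 18:
            log.append((rec.patient_id, "paediatric (age <= 18)"))
            continue
        adm = rec.panels.get(ADMISSION)
        if adm is None:
            log.append((rec.patient_id, "missing admission panel"))
            continue
        dka_fields = _panel_missing_fields(
            adm, ("glucose", "hco3_measured", "ph", "urine_ketones")
        )
        if dka_fields:
            log.append((rec.patient_id, f"missing data: admission {dka_fields[0]}"))
            continue
        if not ab.is_dka(adm):
            log.append((rec.patient_id, "does not meet DKA definition at admission"))
            continue
        h6 = rec.panels.get(H6)
        if h6 is None:
            log.append((rec.patient_id, "missing 6th-hour panel"))
            continue
        missing = _panel_missing_fields(adm, REQUIRED_PANEL_FIELDS)
        if missing:
            log.append((rec.patient_id, f"missing data: admission {missing[0]}"))
            continue
        missing = _panel_missing_fields(h6, REQUIRED_PANEL_FIELDS)
        if missing:
            log.append((rec.patient_id, f"missing data: h6 {missing[0]}"))
            continue
        if rec.los_icu_days is None or not rec.los_icu_days > 0:
            log.append((rec.patient_id, "missing or non-positive LOS-ICU"))
            continue
        included.append(rec)
    return included, log


def compute_deltas(
    record: PatientRecord, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> Dict[str, float]:
    """6th-hour value minus admission value for the tracked variables.

    SIG and BE_Cl are recomputed from the raw panel fields at each timepoint
    before differencing; HCO3 is the gas-derived bicarbonate.
    """
    for tp in (ADMISSION, H6):
        if tp not in record.panels:
            raise MissingDataError(f"panels[{tp}]", record.patient_id)
    adm, h6 = record.panels[ADMISSION], record.panels[H6]

    def derived(panel: TimepointPanel) -> Dict[str, float]:
        panel.require(*REQUIRED_PANEL_FIELDS, context=record.patient_id)
        return {
            "ph": panel.ph,
            "paco2": panel.paco2,
            "hco3": ab.bicarbonate_from_gas(panel.ph, panel.paco2, constants),
            "na": panel.na,
            "cl": panel.cl,
            "sig": ab.strong_ion_gap(panel, constants),
            "lactate": panel.lactate,
            "glucose": panel.glucose,
            "becl": ab.base_excess_chloride(panel.na, panel.cl, constants),
        }

    a, b = derived(adm), derived(h6)
    return {f"delta_{k}": b[k] - a[k] for k in a}


def incidence_per_1000(cases: int, admissions: int) -> float:
    """Cases per 1000 admissions, reported to one decimal."""
    if admissions <= 0:
        raise DomainError("admissions must be positive")
    if cases > admissions:
        raise DomainError("cases cannot exceed admissions")
    return round(1000.0 * cases / admissions, 1)


def group_counts(
    df: pd.DataFrame, condition: pd.Series, group_col: str = "group_label"
) -> pd.DataFrame:
    """Per-group count and percentage of rows satisfying a boolean condition.

    Percentages carry one decimal, e.g. 15 of 22 → 68.2.
    """
    if not condition.index.equals(df.index):
        raise DomainError("condition must be indexed like the cohort table")
    out = []
    for g, sub in df.groupby(group_col, sort=True):
        n = len(sub)
        count = int(condition.loc[sub.index].sum())
        out.append({"group": g, "n": n, "count": count,
                    "pct": round(100.0 * count / n, 1) if n else float("nan")})
    return pd.DataFrame(out)


_PANEL_COLUMNS = (
    "ph", "paco2", "hco3_measured", "sbe_measured", "na", "k", "ca", "mg",
    "cl", "lactate", "albumin", "phosphate", "glucose", "hematocrit",
    "urine_ketones", "urea", "creatinine",
)

_TP_SUFFIX = {ADMISSION: "adm", H6: "h6", H24: "h24"}


def build_table(
    records: Sequence[PatientRecord],
    registry: Optional[FluidRegistry] = None,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> CohortTable:
    """Flatten records into the analysis DataFrame.

    Adds, per patient: raw panel columns suffixed ``_adm``/``_h6``/``_h24``,
    computed SIG / BE_Cl / SBE at admission and 6 h, the delta battery,
    fluid loads over the first 6 h and the regimen-derived ``group_label``.
    Derived columns are pure functions of the raw fields, so rebuilding the
    table from the same records is idempotent.
    """
    registry = registry or FluidRegistry.default()
    rows = []
    for rec in records:
        row: Dict[str, object] = {
            "patient_id": rec.patient_id,
            "age": rec.age_years,
            "sex": rec.sex,
            "bmi": rec.bmi_kg_m2,
            "weight_kg": rec.weight_kg,
            "cci": rec.cci,
            "apache2": rec.apache2,
            "sofa": rec.sofa,
            "nahco3_bolus_mmol": rec.nahco3_bolus_mmol,
            "kcl_mmol": rec.kcl_mmol,
            "insulin_u_per_kg_h": rec.insulin_u_per_kg_h,
            "urine_output_ml_kg_h": rec.urine_output_ml_kg_h,
            "los_icu_days": rec.los_icu_days,
        }
        for tp, suffix in _TP_SUFFIX.items():
            panel = rec.panels.get(tp)
            for colf in _PANEL_COLUMNS:
                row[f"{colf}_{suffix}"] = getattr(panel, colf) if panel else None
        for tp, suffix in ((ADMISSION, "adm"), (H6, "h6")):
            panel = rec.panels.get(tp)
            if panel is not None and not _panel_missing_fields(panel, REQUIRED_PANEL_FIELDS):
                row[f"sig_{suffix}"] = ab.strong_ion_gap(panel, constants)
                row[f"becl_{suffix}"] = ab.base_excess_chloride(panel.na, panel.cl, constants)
                row[f"hco3_calc_{suffix}"] = ab.bicarbonate_from_gas(
                    panel.ph, panel.paco2, constants)
                row[f"sbe_calc_{suffix}"] = ab.standard_base_excess(
                    panel.ph, panel.paco2, constants)
        if ADMISSION in rec.panels and H6 in rec.panels:
            try:
                row.update(compute_deltas(rec, constants))
            except MissingDataError:
                pass
        summary = electrolyte_load(
            rec.administrations, registry, window="first_6h", kcl_mmol=rec.kcl_mmol)
        row["fluid_volume_ml_6h"] = summary.total_volume_ml
        row["administered_na_mmol_6h"] = summary.administered_na_mmol
        row["administered_cl_mmol_6h"] = summary.administered_cl_mmol
        row["na_cl_difference_mmol_6h"] = summary.na_cl_difference_mmol
        if rec.weight_kg:
            row["fluid_ml_kg_h_6h"] = summary.total_volume_ml / rec.weight_kg / 6.0
        else:
            row["fluid_ml_kg_h_6h"] = None
        row["group_label"] = classify_regimen(summary)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("patient_id", drop=False)
        df.index.name = None
    return CohortTable(records=list(records), df=df)
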
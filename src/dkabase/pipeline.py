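"""End-to-end assembly: simulate a cohort to disk, analyse a cohort from disk.

``run_analyze`` is deterministic in its inputs: ingest → inclusion filters →
derived columns (SIG, BE_Cl, deltas, loads, group labels) → two-group
comparison battery at admission and 6 h → LOS correlations → LOS regression
→ report tables and a JSON summary.  All outputs are computed in memory
first and only then written, so a failure never leaves partial output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import stats as st
from .cohort import (
    CohortTable,
    apply_inclusion_filters,
    build_table,
    group_counts,
)
from .errors import DegenerateDataError
from .fluids import FluidRegistry
from .io import read_admins_csv, read_cohort_csv, write_admins_csv, write_cohort_csv
from .stats import DEFAULT_PREDICTORS
from .synthetic import SyntheticCohortConfig, generate_cohort

__all__ = ["AnalysisOptions", "AnalysisReport", "run_analyze", "run_simulate",
           "ADMISSION_CONTINUOUS_VARS", "H6_CONTINUOUS_VARS", "DELTA_LOS_VARS"]

ADMISSION_CONTINUOUS_VARS = (
    "age", "bmi", "cci", "apache2", "sofa",
    "ph_adm", "paco2_adm", "hco3_calc_adm", "sbe_calc_adm", "na_adm",
    "cl_adm", "becl_adm", "k_adm", "lactate_adm", "hematocrit_adm",
    "glucose_adm", "sig_adm", "urine_ketones_adm", "urea_adm", "creatinine_adm",
)
ADMISSION_CATEGORICAL_VARS = ("sex",)
H6_CONTINUOUS_VARS = (
    "fluid_ml_kg_h_6h", "nahco3_bolus_mmol", "kcl_mmol", "insulin_u_per_kg_h",
    "administered_na_mmol_6h", "administered_cl_mmol_6h",
    "na_cl_difference_mmol_6h", "urine_output_ml_kg_h",
    "ph_h6", "paco2_h6", "hco3_calc_h6", "sbe_calc_h6", "na_h6", "cl_h6",
    "becl_h6", "k_h6", "lactate_h6", "hematocrit_h6", "glucose_h6", "sig_h6",
    "urine_ketones_h24", "urea_h24", "creatinine_h24", "los_icu_days",
)
DELTA_LOS_VARS = (
    "delta_ph", "delta_paco2", "delta_hco3", "delta_na", "delta_cl",
    "delta_sig", "delta_lactate", "delta_glucose", "delta_becl",
)


@dataclass
class AnalysisOptions:
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    equal_var: bool = True
    scale_ph_by_100: bool = True
    registry: Optional[FluidRegistry] = None


@dataclass
class AnalysisReport:
    table: CohortTable
    exclusion_log: List[Tuple[str, str]]
    comparison_admission: pd.DataFrame
    comparison_h6: pd.DataFrame
    correlations: pd.DataFrame
    regression: pd.DataFrame
    summary: Dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.comparison_admission.to_csv(out / "comparison_admission.csv", index=False)
        self.comparison_h6.to_csv(out / "comparison_h6.csv", index=False)
        self.correlations.to_csv(out / "correlations_los.csv", index=False)
        self.regression.to_csv(out / "regression_los.csv", index=True,
                               index_label="predictor")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        with open(out / "exclusions.csv", "w", encoding="utf-8") as fh:
            fh.write("patient_id,reason\n")
            for pid, reason in self.exclusion_log:
                fh.write(f"{pid},\"{reason}\"\n")


def _comparison_frame(df, continuous, categorical, options) -> pd.DataFrame:
    rows = []
    groups = sorted(df["group_label"].unique())
    for var in continuous:
        try:
            res = st.compare_groups(df, var, equal_var=options.equal_var)
            rows.append({
                "variable": var, "test_used": res.test_used,
                "statistic": res.statistic, "p_value": res.p_value,
                **{f"summary_{g}": res.group_summaries.get(str(g), "")
                   for g in groups},
            })
        except DegenerateDataError as exc:
            rows.append({"variable": var, "test_used": "not_testable",
                         "statistic": np.nan, "p_value": np.nan,
                         **{f"summary_{g}": str(exc) for g in groups}})
    for var in categorical:
        res = st.compare_groups(df, var, categorical=True)
        rows.append({
            "variable": var, "test_used": res.test_used,
            "statistic": res.statistic, "p_value": res.p_value,
            **{f"summary_{g}": res.group_summaries.get(str(g), "")
               for g in groups},
        })
    return pd.DataFrame(rows)


def run_analyze(cohort_csv, admins_csv, options: Optional[AnalysisOptions] = None
                ) -> AnalysisReport:
    """Run the full deterministic analysis on a cohort + administrations CSV."""
    options = options or AnalysisOptions()
    registry = options.registry or FluidRegistry.default()
    records = read_cohort_csv(cohort_csv)
    admins = read_admins_csv(admins_csv)
    by_patient: Dict[str, list] = {}
    for a in admins:
        by_patient.setdefault(a.patient_id, []).append(a)
    for rec in records:
        rec.administrations = by_patient.get(rec.patient_id, [])

    included, exclusion_log = apply_inclusion_filters(records)
    table = build_table(included, registry)
    df = table.df
    group_sizes = df["group_label"].value_counts().to_dict() if len(df) else {}
    analysable = {g: n for g, n in group_sizes.items() if g in ("GI", "GII")}
    if len(analysable) < 2:
        raise DegenerateDataError(
            f"two-group analysis needs both GI and GII; group sizes: {group_sizes}")
    df = df[df["group_label"].isin(("GI", "GII"))]

    comparison_admission = _comparison_frame(
        df, ADMISSION_CONTINUOUS_VARS, ADMISSION_CATEGORICAL_VARS, options)
    comparison_h6 = _comparison_frame(df, H6_CONTINUOUS_VARS, (), options)

    corr_rows = []
    for var in DELTA_LOS_VARS:
        try:
            r, p = st.correlate_with_los(df, var)
            corr_rows.append({"variable": var, "pearson_r": r, "p_value": p})
        except DegenerateDataError:
            corr_rows.append({"variable": var, "pearson_r": np.nan,
                              "p_value": np.nan})
    correlations = pd.DataFrame(corr_rows)

    reg = st.los_regression(df, predictors=options.predictors,
                            scale_ph_by_100=options.scale_ph_by_100)

    hyperchloremic = group_counts(df, df["becl_adm"] < 0)
    severe_acidosis = group_counts(df, df["ph_adm"] <= 7.0)

    # analyzer-reported vs gas-derived bicarbonate / SBE consistency
    def _discrepancy(measured_col, calc_col):
        sub = df[[measured_col, calc_col]].dropna()
        if not len(sub):
            return None
        return float((sub[measured_col] - sub[calc_col]).abs().mean())

    summary = {
        "n_input": len(records),
        "n_included": len(included),
        "n_excluded": len(exclusion_log),
        "group_sizes": {str(k): int(v) for k, v in group_sizes.items()},
        "hyperchloremic_at_admission": hyperchloremic.to_dict(orient="records"),
        "ph_le_7_0_at_admission": severe_acidosis.to_dict(orient="records"),
        "correlations_los": correlations.to_dict(orient="records"),
        "regression": {
            "outcome": reg.outcome,
            "r_squared": reg.r_squared,
            "durbin_watson": reg.durbin_watson,
            "n": reg.n,
        },
        "analyzer_vs_computed_mean_abs_diff": {
            "hco3_adm": _discrepancy("hco3_measured_adm", "hco3_calc_adm"),
            "sbe_adm": _discrepancy("sbe_measured_adm", "sbe_calc_adm"),
            "hco3_h6": _discrepancy("hco3_measured_h6", "hco3_calc_h6"),
            "sbe_h6": _discrepancy("sbe_measured_h6", "sbe_calc_h6"),
        },
        "registry_labelling_discrepancies": {
            name: {"computed": c, "labelled": l}
            for name, (c, l) in registry.labelling_discrepancies().items()
        },
        "notes": [
            "p-values are two-sided; no multiple-testing correction applied",
        ],
    }
    return AnalysisReport(
        table=table,
        exclusion_log=exclusion_log,
        comparison_admission=comparison_admission,
        comparison_h6=comparison_h6,
        correlations=correlations,
        regression=reg.table.assign(r_squared=reg.r_squared,
                                    durbin_watson=reg.durbin_watson),
        summary=summary,
    )


def run_simulate(config: SyntheticCohortConfig, out_dir) -> Dict:
    """Generate a synthetic cohort and write cohort / administrations /
    ground-truth files to ``out_dir`` (created if missing)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, ground_truth = generate_cohort(config)
    write_cohort_csv(table.records, out / "cohort.csv")
    admins = [a for rec in table.records for a in rec.administrations]
    write_admins_csv(admins, out / "administrations.csv")
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    ground_truth["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
    return ground_truth
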
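# File formats

All interchange files are plain UTF-8 CSV with a header row, `.` as the
decimal separator and empty cells for missing values. Writers emit
shortest-round-trip float representations, so a write/read cycle is
byte-identical. Readers validate the header and every cell; violations raise
`SchemaError` naming the file, row and column (CLI exit code 2).

## Cohort CSV (wide; one row per patient)

Produced by `dkabase simulate` as `cohort.csv`; consumed by
`dkabase analyze --cohort`. API: `read_cohort_csv` / `write_cohort_csv`.

Identifier and demographics:

| column | type | notes |
|---|---|---|
| `patient_id` | string | required, non-empty |
| `age_years` | float | required |
| `sex` | string | defaults to `unknown` if empty |
| `bmi_kg_m2` | float | optional |
| `weight_kg` | float | optional (needed for per-kg fluid rates) |
| `cci` | int | Charlson comorbidity index, optional |
| `apache2` | int | optional |
| `sofa` | int | optional |
| `nahco3_bolus_mmol` | float | defaults to 0 if empty |
| `kcl_mmol` | float | potassium chloride additive, defaults to 0 |
| `insulin_u_per_kg_h` | float | optional |
| `urine_output_ml_kg_h` | float | optional |
| `los_icu_days` | float | ICU length of stay |

Panel columns repeat for the three timepoints with suffixes `_adm`
(admission), `_h6` (6th hour) and `_h24` (24th hour). A timepoint with all
cells empty means the panel was not taken. Base names and units:

| base column | type | unit / range |
|---|---|---|
| `ph` | float | validated to [6.5, 7.8] |
| `paco2_mmhg` | float | > 0 |
| `hco3_mmol_l` | float | analyzer-reported bicarbonate (optional; the pipeline also recomputes HCO3 from pH and PaCO2) |
| `sbe_mmol_l` | float | analyzer-reported standard base excess (optional) |
| `na_mmol_l` | float | ≥ 0 |
| `k_mmol_l` | float | ≥ 0 |
| `ca_meq_l` | float | ionized calcium as charge concentration |
| `mg_meq_l` | float | magnesium as charge concentration |
| `cl_mmol_l` | float | ≥ 0 |
| `lactate_mmol_l` | float | ≥ 0 |
| `albumin_g_l` | float | grams per litre (not g/dL) |
| `phosphate_mmol_l` | float | ≥ 0 |
| `glucose_mg_dl` | float | ≥ 0 |
| `hct_pct` | float | hematocrit, percent |
| `urine_ketones` | int | ordinal 0–4 dipstick grade |
| `urea_mg_dl` | float | ≥ 0 |
| `creatinine_mg_dl` | float | ≥ 0 |

## Panels CSV (long; one row per patient-timepoint)

API: `read_panels_csv` / `write_panels_csv`. Columns: `patient_id`,
`timepoint` (one of `admission`, `h6`, `h24`), then the panel base columns
above without suffix.

## Administrations CSV

Produced by `dkabase simulate` as `administrations.csv`; consumed by
`dkabase analyze --admins`. API: `read_admins_csv` / `write_admins_csv`.

| column | type | notes |
|---|---|---|
| `patient_id` | string | joins to the cohort file |
| `fluid_name` | string | must exist in the fluid registry |
| `volume_ml` | float | required |
| `window` | string | `first_6h` (default if empty) or `later` |

## Fluid registry CSV

API: `FluidRegistry.from_csv` / `to_csv`. Required columns: `name`,
`na_mmol_per_l`, `cl_mmol_per_l`, `bicarbonate_mmol_per_l`. Optional:
`dextrose_flag` (0/1), `labelled_na_cl_difference` (the difference printed on
the product label, kept separately because two stock fluids carry labels that
disagree with their own composition; see `FluidRegistry.labelling_discrepancies`).

## Simulator config JSON

`dkabase simulate --config file.json` accepts a JSON object whose keys are
fields of `SyntheticCohortConfig` (see `docs/methods.md` for meanings and
defaults). Unknown keys raise `ConfigError` (exit code 4). `--seed` on the
command line overrides the file's `seed`.

## Analysis output directory

`dkabase analyze --out DIR` (or `AnalysisReport.write`) writes:

- `comparison_admission.csv`, `comparison_h6.csv` — one row per variable:
  `variable`, `test_used` (`student_t`, `welch_t`, `mann_whitney`,
  `chi_square`, `fisher_exact` or `not_testable`), `statistic`, `p_value`,
  `summary_GI`, `summary_GII` (mean ± sd for normal data, median (min–max)
  otherwise).
- `correlations_los.csv` — `variable`, `pearson_r`, `p_value` for each 6-hour
  delta against ICU length of stay.
- `regression_los.csv` — `predictor`, `coef`, `ci_low`, `ci_high`, `p_value`,
  plus the model-level `r_squared` and `durbin_watson` repeated per row.
- `exclusions.csv` — `patient_id`, `reason` for every excluded record.
- `summary.json` — counts, group sizes, hyperchloremia and severe-acidemia
  proportions per group, analyzer-vs-computed HCO3/SBE mean absolute
  differences, registry labelling discrepancies and method notes.

## Simulation output directory

`dkabase simulate --out DIR` writes `cohort.csv`, `administrations.csv` and
`ground_truth.json` (the seed, full config with its SHA-256, the generating
LOS coefficients and per-patient strong-ion-gap decay targets).
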
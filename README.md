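# dkabase

Quantitative acid-base analysis of fluid therapy in diabetic ketoacidosis
(DKA): a library, synthetic-cohort simulator and analysis pipeline built
around the Stewart/Figge partitioning of metabolic acidosis.

## The science in one paragraph

A DKA patient arrives with a metabolic acidosis caused almost entirely by
unmeasured anions — ketoacids — which the **strong ion gap (SIG)**
quantifies. Over the first hours of treatment, insulin clears the ketoacids
while resuscitation fluid loads the patient with sodium and chloride. A
chloride-rich regimen (0.9% saline: Na − Cl difference of 0 mmol/L) replaces
the resolving ketoacidosis with an iatrogenic **hyperchloremic** acidosis,
visible as a falling chloride component of base excess,
`BE_Cl = Na − Cl − 32`. A balanced regimen (e.g. a balanced crystalloid with
a per-litre Na − Cl difference of 37–43 mmol/L) avoids this substitution.
`dkabase` implements the arithmetic to separate these components on any
blood-gas panel, the bookkeeping to classify fluid regimens, the statistics
to compare groups, and a mass-balance simulator that generates coherent
synthetic cohorts with known ground truth.

## Worked example

Partition the acidosis of a single admission panel
(`examples/01_strong_ion_gap.py`):

```python
from dkabase import (TimepointPanel, base_excess_chloride, bicarbonate_from_gas,
                     classify_chloremia, standard_base_excess, strong_ion_gap)

panel = TimepointPanel(
    ph=7.08, paco2=17.0,
    na=136.0, k=4.8, ca=4.6, mg=1.7, cl=106.0, lactate=1.8,
    albumin=38.0, phosphate=1.4, glucose=430.0, urine_ketones=3,
).validate()

print(bicarbonate_from_gas(panel.ph, panel.paco2))
print(standard_base_excess(panel.ph, panel.paco2))
print(strong_ion_gap(panel))
print(base_excess_chloride(panel.na, panel.cl))
```

Output of the example script:

```
computed HCO3          :   4.98 mmol/L   (from pH and PaCO2)
standard base excess   : -22.44 mmol/L   (overall metabolic acidosis)
strong ion gap (SIG)   :  22.80 mmol/L   (unmeasured anions, e.g. ketoacids)
BE_Cl = Na - Cl - 32   :  -2.00 mmol/L   (hyperchloremic)

At admission the acidosis is dominated by unmeasured anions (large SIG)
while the chloride component is still near zero.
```

## Library map

| module | contents |
|---|---|
| `dkabase.acid_base` | `TimepointPanel`, HCO3/SBE/pH gas arithmetic, `strong_ion_gap`, `base_excess_chloride`, `is_dka`, `AcidBaseConstants` |
| `dkabase.fluids` | `FluidRegistry` (10 stock fluids), `mix_fluids`, `electrolyte_load`, `classify_regimen` (GI = chloride-rich, GII = balanced) |
| `dkabase.cohort` | `PatientRecord`, inclusion filters with exclusion log, six-hour deltas, `build_table` → pandas DataFrame, incidence and group counts |
| `dkabase.stats` | normality-gated t / Mann–Whitney comparisons, chi-square / Fisher, LOS correlation and OLS regression (95% CI, R², Durbin–Watson), noncentral-t power |
| `dkabase.synthetic` | `SyntheticCohortConfig`, `generate_cohort` — seeded two-arm cohorts with recorded ground truth |
| `dkabase.io` | lossless CSV readers/writers (`docs/SCHEMAS.md`) |
| `dkabase.pipeline` | `run_simulate`, `run_analyze`, `AnalysisReport` |

All of this is importable; the `dkabase` command is a thin wrapper over
`dkabase.pipeline`:

```sh
dkabase simulate --seed 11 --out sim/
dkabase analyze --cohort sim/cohort.csv --admins sim/administrations.csv --out report/
dkabase report --summary report/summary.json
```

Exit codes: 0 success, 2 schema violation, 3 degenerate data (e.g. a
single-arm cohort), 4 bad configuration, 1 other package errors.

The `examples/` directory walks the pieces in order: single-panel
partitioning, fluid electrolyte loads, cohort simulation, and the full
simulate-to-report pipeline.

## Tests

```sh
python -m pytest -q tests/
```

The suite (159 tests) checks the frozen desk values, property-based
invariants (hypothesis, derandomized), and oracle equivalence: Mann–Whitney
against exhaustive permutation enumeration, Fisher against hypergeometric
enumeration, power against Monte-Carlo simulation, and the strong ion gap
against an independent term-by-term computation.

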
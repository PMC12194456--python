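# Methods

This note documents the quantitative model behind `dkabase`: the acid-base
arithmetic, the fluid bookkeeping, the statistical rules and the synthetic
cohort generator, including its assumptions and known limitations.

## Acid-base model (Stewart/Figge)

All gas arithmetic is carbonic-acid Henderson–Hasselbalch with
`pK = 6.1` and CO2 solubility `S = 0.0307 mmol/L/mmHg`:

```
HCO3 = S · PaCO2 · 10^(pH − 6.1)
```

The metabolic state is decomposed into three additive components:

- **Standard base excess (SBE)**, Van Slyke form:
  `SBE = 0.9287 · (HCO3 − 24.4 + 14.83 · (pH − 7.40))`.
- **Chloride component**: `BE_Cl = Na − Cl − 32` (mmol/L). Negative values
  are classified hyperchloremic, positive hypochloremic, zero normochloremic.
- **Unmeasured anions (strong ion gap)**:

  ```
  SIDa = Na + K + Ca + Mg − Cl − lactate        (Ca, Mg in mEq/L)
  SIG  = SIDa − HCO3 − albumin charge − phosphate charge
  albumin charge   = Alb[g/L] · (0.123 · pH − 0.631)
  phosphate charge = Pi[mmol/L] · (0.309 · pH − 0.469)
  ```

All coefficients live in the frozen dataclass `AcidBaseConstants`; every
function accepts an alternative constants object for sensitivity analyses.
For the reference panel (Na 140, K 4.0, Ca 4.4 mEq/L, Mg 1.6 mEq/L, Cl 105,
lactate 1.0, pH 7.40, PaCO2 40, albumin 42 g/L, phosphate 1.2 mmol/L) the
package computes SIG = 5.5907 mmol/L; the unit tests freeze this value.

**DKA definition** (all strict inequalities except ketones): glucose
> 200 mg/dL, computed HCO3 < 15 mmol/L, pH < 7.30, urine ketones ≥ 2.

## Fluids and regimen classification

Each fluid is a composition in mmol/L (Na, Cl, bicarbonate). The
discriminating quantity of a regimen is its six-hour **sodium-chloride
difference**: total infused Na minus total infused Cl in mmol. A regimen is

- **GI (chloride-rich)** if the fluid-borne difference is exactly 0 mmol
  (e.g. any volume of 0.9% or 0.45% saline, or pure dextrose);
- **GII (balanced)** if it exceeds 32 mmol, the same constant that anchors
  `BE_Cl`;
- unclassified otherwise.

Potassium chloride added to bags is booked separately
(`additive_cl_mmol`) and excluded from the classification by default,
because it is titrated to potassium, not chosen as a volume strategy; pass
`include_additive_cl=True` to `electrolyte_load` to include it. The default
registry keeps the manufacturer-labelled Na−Cl difference alongside the
composition; `labelling_discrepancies()` reports the two stock fluids whose
label disagrees with their own composition arithmetic.

## Cohort analytics

Inclusion requires age > 18 (strict), the DKA definition at admission, a
complete required panel (pH, PaCO2, Na, K, Ca, Mg, Cl, lactate, albumin,
phosphate, glucose) at admission and at 6 h, and a positive ICU length of
stay; every exclusion is logged with its reason. Six-hour deltas are
h6 minus admission, with HCO3, SBE, SIG and BE_Cl recomputed from the raw
panels rather than taken from analyzer fields. The analyzer-reported HCO3
and SBE, when present, are compared against the gas-derived values and the
mean absolute difference is reported in `summary.json`.

## Statistical rules

- **Two-group continuous comparison**: Shapiro–Wilk on each group; if both
  p ≥ 0.05, Student's t (Welch with `equal_var=False`), otherwise
  Mann–Whitney U. Groups with fewer than 3 observations, or constant in
  both groups, are not testable (`DegenerateDataError`).
- **Categorical**: chi-square unless any expected cell count is below 5,
  then Fisher's exact test.
- **LOS model**: OLS of ICU length of stay on age, BMI, APACHE II, SOFA and
  the six-hour deltas of pH (×100), PaCO2, HCO3, Na, Cl, lactate, SIG and
  glucose, with intercept; reported with 95% CIs, R² and Durbin–Watson.
  Exact collinearity is detected by QR rank check and raises
  `CollinearityError` naming the offending columns.
- **Power**: two-sided two-sample t-test power from the noncentral t
  distribution with `nc = (Δ/σ)·sqrt(n1·n2/(n1+n2))` and `df = n1+n2−2`.
  At zero effect this returns exactly α.

The nonparametric backends (scipy) are verified in the test suite against
independent oracles: full permutation enumeration for Mann–Whitney and
hypergeometric enumeration for Fisher's exact test; the power function is
verified against a 10,000-replicate Monte-Carlo simulation.

## Synthetic cohort generator

The generator produces a two-arm cohort (default 22 GI / 13 GII patients)
from a single seeded `numpy` generator stream; identical configs give
byte-identical output.

### Admission panels

pH, PaCO2, electrolytes, albumin, phosphate, lactate and a target SIG are
drawn from truncated normals (defaults: pH 7.10 ± 0.10, PaCO2 16.5 ± 6 mmHg,
SIG 19 ± 6 mmol/L). HCO3 is *computed* from the drawn gas pair, and chloride
is *solved* from the SIG equation, so every panel is internally coherent:
`strong_ion_gap(panel)` equals the drawn target to machine precision. Draws
are rejected until the panel meets the DKA definition (with computed
HCO3 in [2, 15)).

### Six-hour evolution

Let `V = 0.2 · weight` (L) be the distribution volume, `V_inf` the infused
volume, `r = 0.6` the retained-volume fraction and `e = 0.3` the fraction of
the infused Na/Cl load excreted in urine. Mass balance gives

```
Cl6 = (Cl0·V + (1−e)·Cl_load) / (V + r·V_inf)
Na6 = (Na0·V + (1−e)·(Na_load + NaHCO3 bolus)) / (V + r·V_inf)
```

and the same dilution factor `V/(V + r·V_inf)` scales K (then shifted down
0.7 mmol/L for insulin), Ca, Mg, albumin, phosphate and hematocrit. The
strong ion gap decays exponentially (`SIG6 = SIG0·e^(−0.12·6)`, the ketoacid
clearance under insulin). SBE moves additively:

```
SBE6 = SBE0 + (BE_Cl6 − BE_Cl0) + (SIG0 − SIG6) + bolus/V
```

The respiratory side follows Winter's compensation
(`PaCO2 = 1.5·HCO3 + 8`) *offset by the patient's admission deviation from
the Winter line*, plus Gaussian noise (sd 2 mmHg) and a 10 mmHg floor.
Preserving the admission offset, rather than snapping to the Winter line,
makes the zero-intervention state an exact fixed point of the evolution —
a property the test suite checks to 1e-9 on twelve fields. pH, HCO3 and
PaCO2 are closed by fixed-point iteration of the gas system (the loop gain
is ≈ −0.1, so it converges in a handful of steps).

Rare extreme draws (very large chloride load on a very acidemic patient)
can push the closed gas system outside survivable ranges; the evolved pH is
therefore clamped to `[ph_6h_floor, ph_6h_ceiling]` (defaults 6.8–7.7),
never clamping past the admission value, and HCO3 is recomputed from the
clamped gas pair to preserve Henderson–Hasselbalch coherence. At the
default parameters this touches on the order of 1 in 10⁴ patients.

ICU length of stay is generated as
`LOS = 2.0 + 0.2·ΔCl + 0.3·Δlactate + N(0, 0.5)`, floored at 1 day; the
coefficients are recorded in `ground_truth.json` so recovery can be tested.

### What the generator reproduces, and what it does not

Reproduced (verified in `tests/` and `scripts/acceptance.py`):

- the qualitative six-hour contrast — the chloride-rich arm ends with
  higher Cl, lower BE_Cl, lower pH and lower PaCO2 (all four directions in
  ≥ 95% of seeds at 200 patients/arm);
- exact GI/GII separation of the infused Na−Cl difference (0 versus a
  median within 95–263 mmol);
- SIG-dominated acidosis at admission turning partly hyperchloremic by 6 h;
- OLS recovery of the generating LOS coefficient (95% CI covers the truth
  in ≥ 90% of 100 seeds).

Not reproduced / simplifications:

- Absolute 6-hour HCO3, SBE and PaCO2 run *higher* than is typical for real
  cohorts at that timepoint: the additive SBE model credits the full
  cleared SIG back as base, i.e. ketoacid anions are treated as
  metabolizable without loss. Group contrasts are realistic; absolute
  recovery speed is optimistic.
- Part of the between-arm chloride contrast is driven by the arm *volume*
  difference (the balanced arm receives more fluid and dilutes more), not
  only by the fluid composition; setting the urinary excretion fraction to
  1 removes the load-driven part and leaves exactly the dilution-only
  prediction (tested to rtol 1e-12).
- No renal chloride autoregulation, no time-resolved kinetics inside the
  0–6 h window, no treatment feedback (fluid choice does not respond to
  evolving chemistry), and 24-hour panels carry only urea, creatinine and
  ketone trends, not a full second evolution.
- Demographics, severity scores and the LOS error are independent draws;
  real confounding between severity and fluid choice is absent.

## Numerical choices

- Rejection sampling for truncated normals (bounds far from the mean in all
  uses; hard iteration caps raise `SimulationError` rather than loop).
- The gas fixed point iterates to |ΔpH| < 1e-12 with a 200-step cap; HCO3
  is kept ≥ 0.3 mmol/L during iteration to keep logarithms defined.
- CSV writers emit shortest-round-trip (`repr`) floats; round trips are
  byte-identical and exercised in the test suite.
- Proportions and incidences are rounded to one decimal at the reporting
  boundary only; all internal arithmetic is double precision.
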
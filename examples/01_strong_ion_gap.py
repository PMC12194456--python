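"""Quantify the three components of a metabolic acidosis in one blood panel.

A single arterial panel is enough to split base excess into a chloride
effect (BE_Cl), an unmeasured-anion effect (strong ion gap, SIG) and the
remainder.  This example evaluates a typical DKA admission panel.
"""

from dkabase import (
    TimepointPanel,
    base_excess_chloride,
    bicarbonate_from_gas,
    classify_chloremia,
    standard_base_excess,
    strong_ion_gap,
)

panel = TimepointPanel(
    ph=7.08, paco2=17.0,
    na=136.0, k=4.8, ca=4.6, mg=1.7, cl=106.0, lactate=1.8,
    albumin=38.0, phosphate=1.4, glucose=430.0, urine_ketones=3,
).validate()

hco3 = bicarbonate_from_gas(panel.ph, panel.paco2)
sbe = standard_base_excess(panel.ph, panel.paco2)
sig = strong_ion_gap(panel)
becl = base_excess_chloride(panel.na, panel.cl)

print(f"computed HCO3          : {hco3:6.2f} mmol/L   (from pH and PaCO2)")
print(f"standard base excess   : {sbe:6.2f} mmol/L   (overall metabolic acidosis)")
print(f"strong ion gap (SIG)   : {sig:6.2f} mmol/L   (unmeasured anions, e.g. ketoacids)")
print(f"BE_Cl = Na - Cl - 32   : {becl:6.2f} mmol/L   ({classify_chloremia(becl)})")
print()
print("At admission the acidosis is dominated by unmeasured anions (large SIG)")
print("while the chloride component is still near zero.")
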
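"""Compare the electrolyte load of a saline-based and a balanced regimen.

The sodium-chloride difference of the infused fluid (Na minus Cl, in mmol)
is what separates a chloride-rich regimen (difference 0) from a balanced
one (difference above 32 mmol over the first six hours).
"""

from dkabase import (
    FluidAdministration,
    FluidRegistry,
    classify_regimen,
    electrolyte_load,
    mix_fluids,
    sodium_chloride_difference,
)

registry = FluidRegistry.default()

print("Na-Cl difference per litre of common fluids:")
for name in ("nacl_0.9", "nacl_0.45", "isolyte", "isolyte_s", "half_saline_bicarb"):
    f = registry.get(name)
    print(f"  {name:20s} Na {f.na_mmol_per_l:5.0f}  Cl {f.cl_mmol_per_l:5.0f}"
          f"  diff {sodium_chloride_difference(f):5.0f} mmol/L")

for label, mismatch in registry.labelling_discrepancies().items():
    print(f"  note: {label} computed diff {mismatch[0]:g} differs from"
          f" labelled {mismatch[1]:g}")

# two regimens for the same patient, first six hours
saline_regimen = [FluidAdministration("p1", "nacl_0.9", 3000.0)]
balanced_regimen = [FluidAdministration("p1", "isolyte", 3300.0)]

for title, regimen in (("saline", saline_regimen), ("balanced", balanced_regimen)):
    s = electrolyte_load(regimen, registry)
    print(f"\n{title} regimen over 6 h:")
    print(f"  volume {s.total_volume_ml:.0f} mL, Na {s.administered_na_mmol:.1f} mmol,"
          f" Cl {s.administered_cl_mmol:.1f} mmol")
    print(f"  Na-Cl difference {s.na_cl_difference_mmol:.1f} mmol"
          f" -> classified {classify_regimen(s)}")

# a 2:1 mixture behaves like its volume-weighted composition
mixture = mix_fluids([(registry.get("nacl_0.9"), 2000.0),
                      (registry.get("dextrose5"), 1000.0)])
print(f"\n2 L saline + 1 L dextrose 5% mixes to Na {mixture.na_mmol_per_l:.1f},"
      f" Cl {mixture.cl_mmol_per_l:.1f} mmol/L")
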
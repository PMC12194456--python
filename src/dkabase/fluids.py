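"""Intravenous fluid compositions and regimen-level electrolyte accounting.

Each fluid is described by its per-litre Na and Cl content; the per-litre
``Na − Cl`` difference determines whether a fluid is chloride-rich (difference
zero, like 0.9% NaCl at 154/154) or balanced (positive difference, like
Isolyte at 140/103).  Summed over a regimen, the administered Na − Cl
difference in millimoles classifies the regimen into the chloride-rich arm
(GI, difference exactly 0) or the chloride-non-rich arm (GII, difference
> 32 mmol).

KCl additives carry chloride but are booked in a separate additive field so
that fluid-only loads remain comparable across regimens; a switch merges them
for sensitivity analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import DomainError, RegistryError, SchemaError

__all__ = [
    "FluidComposition",
    "FluidAdministration",
    "RegimenSummary",
    "FluidRegistry",
    "sodium_chloride_difference",
    "mix_fluids",
    "electrolyte_load",
    "classify_regimen",
    "GROUP_GI",
    "GROUP_GII",
    "GROUP_UNCLASSIFIED",
    "GII_DIFFERENCE_THRESHOLD_MMOL",
]

GROUP_GI = "GI"
GROUP_GII = "GII"
GROUP_UNCLASSIFIED = "unclassified"

#: Regimens with an administered Na-Cl difference strictly above this (mmol)
#: belong to the chloride-non-rich arm.
GII_DIFFERENCE_THRESHOLD_MMOL = 32.0


@dataclass(frozen=True)
class FluidComposition:
    """Per-litre electrolyte content of a named intravenous fluid.

    ``labelled_na_cl_difference`` records the Na-Cl difference stated on the
    source label/protocol where one exists; for most fluids it equals
    ``na - cl``, but compounded or colloid products are sometimes labelled
    with a difference that their nominal Na/Cl content does not reproduce.
    The computed and labelled values are both kept; see
    :meth:`FluidRegistry.labelling_discrepancies`.
    """

    name: str
    na_mmol_per_l: float
    cl_mmol_per_l: float
    bicarbonate_mmol_per_l: float = 0.0
    dextrose_flag: bool = False
    labelled_na_cl_difference: Optional[float] = None

    def __post_init__(self):
        for f in ("na_mmol_per_l", "cl_mmol_per_l", "bicarbonate_mmol_per_l"):
            if getattr(self, f) < 0:
                raise DomainError(f"{self.name}: {f} must be non-negative")


@dataclass(frozen=True)
class FluidAdministration:
    """A volume of a named fluid given to one patient in one time window."""

    patient_id: str
    fluid_name: str
    volume_ml: float
    window: str = "first_6h"  # or "later"

    def __post_init__(self):
        if self.volume_ml < 0:
            raise DomainError(f"volume_ml must be non-negative, got {self.volume_ml}")
        if self.window not in ("first_6h", "later"):
            raise DomainError(f"window must be 'first_6h' or 'later', got {self.window!r}")


@dataclass(frozen=True)
class RegimenSummary:
    """Electrolyte loads of one patient's fluid regimen in one window.

    ``na_cl_difference_mmol`` is always ``administered_na_mmol −
    administered_cl_mmol`` over fluids only; bicarbonate boluses and KCl
    additives are tracked separately.
    """

    total_volume_ml: float
    administered_na_mmol: float
    administered_cl_mmol: float
    na_cl_difference_mmol: float
    bicarbonate_mmol: float = 0.0
    additive_cl_mmol: float = 0.0
    group_label: str = GROUP_UNCLASSIFIED


# The ten fluids of the study protocol.  Na/Cl per litre as labelled; the
# compounded half-saline + bicarbonate fluid and 20% albumin carry labelled
# differences (50 and 0) that their nominal Na/Cl do not reproduce — both
# values are preserved and the discrepancy is surfaced, never silently fixed.
_DEFAULT_FLUIDS: Tuple[FluidComposition, ...] = (
    FluidComposition("nacl_0.9", 154, 154, labelled_na_cl_difference=0),
    FluidComposition("dextrose5_nacl_0.9", 154, 154, dextrose_flag=True,
                     labelled_na_cl_difference=0),
    FluidComposition("nacl_0.45", 77, 77, labelled_na_cl_difference=0),
    FluidComposition("dextrose5_nacl_0.45", 77, 77, dextrose_flag=True,
                     labelled_na_cl_difference=0),
    FluidComposition("dextrose5", 0, 0, dextrose_flag=True,
                     labelled_na_cl_difference=0),
    FluidComposition("albumin20", 125, 100, labelled_na_cl_difference=0),
    FluidComposition("hes6", 154, 154, labelled_na_cl_difference=0),
    # 935 mL 0.45% NaCl compounded with 65 mL of 8.4% NaHCO3 (65 mmol).
    FluidComposition("half_saline_bicarb", 143, 83, bicarbonate_mmol_per_l=65,
                     labelled_na_cl_difference=50),
    FluidComposition("isolyte", 140, 103, labelled_na_cl_difference=37),
    FluidComposition("isolyte_s", 141, 98, labelled_na_cl_difference=43),
)


class FluidRegistry:
    """Name-indexed collection of :class:`FluidComposition` entries."""

    def __init__(self, fluids: Iterable[FluidComposition] = ()):
        self._fluids: Dict[str, FluidComposition] = {}
        for f in fluids:
            self.add(f)

    def add(self, fluid: FluidComposition) -> None:
        if fluid.name in self._fluids:
            raise RegistryError(f"duplicate fluid name: {fluid.name}")
        self._fluids[fluid.name] = fluid

    def get(self, name: str) -> FluidComposition:
        try:
            return self._fluids[name]
        except KeyError:
            raise RegistryError(
                f"unknown fluid: {name!r} (registered: {sorted(self._fluids)})"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._fluids

    def __iter__(self):
        return iter(self._fluids.values())

    def __len__(self) -> int:
        return len(self._fluids)

    @classmethod
    def default(cls) -> "FluidRegistry":
        """Registry preloaded with the ten study-protocol fluids."""
        return cls(_DEFAULT_FLUIDS)

    def labelling_discrepancies(self) -> Dict[str, Tuple[float, float]]:
        """Fluids whose labelled Na-Cl difference differs from ``na - cl``.

        Returns ``{name: (computed, labelled)}``; reported, never corrected.
        """
        out = {}
        for f in self:
            if f.labelled_na_cl_difference is not None:
                computed = sodium_chloride_difference(f)
                if computed != f.labelled_na_cl_difference:
                    out[f.name] = (computed, f.labelled_na_cl_difference)
        return out

    # ---- CSV interchange -------------------------------------------------

    _COLUMNS = ("name", "na_mmol_per_l", "cl_mmol_per_l", "bicarbonate_mmol_per_l")

    @classmethod
    def from_csv(cls, path) -> "FluidRegistry":
        reg = cls()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            missing = set(cls._COLUMNS) - set(reader.fieldnames or ())
            if missing:
                raise SchemaError(f"{path}: missing registry columns {sorted(missing)}")
            for i, row in enumerate(reader, start=2):
                try:
                    reg.add(FluidComposition(
                        name=row["name"],
                        na_mmol_per_l=float(row["na_mmol_per_l"]),
                        cl_mmol_per_l=float(row["cl_mmol_per_l"]),
                        bicarbonate_mmol_per_l=float(row["bicarbonate_mmol_per_l"] or 0),
                        dextrose_flag=(row.get("dextrose_flag", "") or "").lower()
                        in ("1", "true", "yes"),
                        labelled_na_cl_difference=(
                            float(row["labelled_na_cl_difference"])
                            if row.get("labelled_na_cl_difference") not in (None, "")
                            else None
                        ),
                    ))
                except (ValueError, DomainError) as exc:
                    raise SchemaError(f"{path} row {i}: {exc}") from exc
        return reg

    def to_csv(self, path) -> None:
        cols = list(self._COLUMNS) + ["dextrose_flag", "labelled_na_cl_difference"]
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(cols)
            for f in self:
                writer.writerow([
                    f.name, f.na_mmol_per_l, f.cl_mmol_per_l,
                    f.bicarbonate_mmol_per_l, int(f.dextrose_flag),
                    "" if f.labelled_na_cl_difference is None
                    else f.labelled_na_cl_difference,
                ])


def sodium_chloride_difference(fluid: FluidComposition) -> float:
    """Per-litre Na − Cl difference (mmol/L) of a fluid."""
    return fluid.na_mmol_per_l - fluid.cl_mmol_per_l


def mix_fluids(
    components: Sequence[Tuple[FluidComposition, float]],
    name: str = "mixture",
) -> FluidComposition:
    """Volume-weighted mixture of fluids (no excess-volume chemistry).

    ``components`` is a sequence of (fluid, volume_ml) pairs with positive
    total volume.
    """
    if not components:
        raise DomainError("mix_fluids: empty component list")
    total = sum(v for _, v in components)
    if not total > 0:
        raise DomainError("mix_fluids: total volume must be positive")
    na = sum(f.na_mmol_per_l * v for f, v in components) / total
    cl = sum(f.cl_mmol_per_l * v for f, v in components) / total
    bicarb = sum(f.bicarbonate_mmol_per_l * v for f, v in components) / total
    return FluidComposition(
        name=name,
        na_mmol_per_l=na,
        cl_mmol_per_l=cl,
        bicarbonate_mmol_per_l=bicarb,
        dextrose_flag=any(f.dextrose_flag for f, _ in components),
    )


def electrolyte_load(
    admins: Iterable[FluidAdministration],
    registry: FluidRegistry,
    window: str = "first_6h",
    kcl_mmol: float = 0.0,
    include_additive_cl: bool = False,
) -> RegimenSummary:
    """Sum Na/Cl loads (mmol) over a patient's administrations in a window.

    Loads are linear in volume: ``Na = sum(volume_L * na_mmol_per_l)`` and
    likewise for Cl; the difference is fluids-only.  ``kcl_mmol`` chloride is
    booked in ``additive_cl_mmol`` and only merged into the Cl load when
    ``include_additive_cl`` is set.
    """
    total_ml = 0.0
    na = 0.0
    cl = 0.0
    bicarb = 0.0
    for a in admins:
        if a.window != window:
            continue
        f = registry.get(a.fluid_name)
        v_l = a.volume_ml / 1000.0
        total_ml += a.volume_ml
        na += v_l * f.na_mmol_per_l
        cl += v_l * f.cl_mmol_per_l
        bicarb += v_l * f.bicarbonate_mmol_per_l
    if include_additive_cl:
        cl += kcl_mmol
    return RegimenSummary(
        total_volume_ml=total_ml,
        administered_na_mmol=na,
        administered_cl_mmol=cl,
        na_cl_difference_mmol=na - cl,
        bicarbonate_mmol=bicarb,
        additive_cl_mmol=kcl_mmol,
    )


def classify_regimen(summary: RegimenSummary) -> str:
    """Arm assignment from the fluids-only Na-Cl difference (mmol).

    Exactly zero → GI (chloride-rich); strictly above 32 mmol → GII
    (chloride-non-rich); anything between (or negative) is unclassified —
    the protocol defines no arm for that gap.
    """
    d = summary.na_cl_difference_mmol
    if d == 0:
        return GROUP_GI
    if d > GII_DIFFERENCE_THRESHOLD_MMOL:
        return GROUP_GII
    return GROUP_UNCLASSIFIED


def with_group_label(summary: RegimenSummary) -> RegimenSummary:
    """Return a copy of *summary* with its group label filled in."""
    return replace(summary, group_label=classify_regimen(summary))
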
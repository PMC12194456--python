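"""Physicochemical (Stewart/Figge) acid-base computations.

The quantitative approach treats plasma pH as determined by the strong ion
difference, the total weak acids (albumin, phosphate) and PaCO2.  Two derived
quantities drive the analysis here:

* the **strong ion gap** (SIG), the apparent strong ion difference
  ``Na + K + Ca + Mg - Cl - lactate`` minus the effective buffering charges
  (bicarbonate, albuminate, phosphate).  A positive SIG marks unmeasured
  anions — in diabetic ketoacidosis, essentially beta-hydroxybutyrate.
* the **base-excess chloride** (BE_Cl), ``Na - Cl - 32`` mmol/L, which
  isolates the acidifying effect of chloride relative to sodium.  Negative
  values indicate hyperchloraemia, positive values hypochloraemia.

All formula evaluations are unclamped: validation happens at ingest, not in
the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import DomainError, MissingDataError

__all__ = [
    "AcidBaseConstants",
    "TimepointPanel",
    "DEFAULT_CONSTANTS",
    "bicarbonate_from_gas",
    "albumin_charge",
    "phosphate_charge",
    "apparent_strong_ion_difference",
    "strong_ion_gap",
    "base_excess_chloride",
    "classify_chloremia",
    "standard_base_excess",
    "is_dka",
    "meq_from_mmol_divalent",
]


@dataclass(frozen=True)
class AcidBaseConstants:
    """Constants of the Henderson–Hasselbalch, Figge and Van Slyke relations.

    Parameters
    ----------
    co2_solubility_coeff : mmol/L per mmHg
        Plasma CO2 solubility in the Henderson–Hasselbalch equation.  The
        standard value is 0.0307; see ``docs/methods.md`` for why this is the
        default rather than a smaller printed variant sometimes seen.
    pk : unitless
        Apparent pK of the carbonic acid system (6.1).
    reference_na_cl_difference : mmol/L
        The sodium–chloride difference of normal plasma (32); BE_Cl is the
        deviation of Na − Cl from this reference.
    albumin_slope, albumin_intercept : per-pH-unit, unitless
        Figge linearisation of the albuminate charge per g/L of albumin.
    phosphate_slope, phosphate_intercept
        Same for inorganic phosphate per mmol/L.
    vanslyke_scale, vanslyke_hco3_ref, vanslyke_ph_slope
        Van Slyke standard-base-excess approximation constants.
    """

    co2_solubility_coeff: float = 0.0307
    pk: float = 6.1
    reference_na_cl_difference: float = 32.0
    albumin_slope: float = 0.123
    albumin_intercept: float = 0.631
    phosphate_slope: float = 0.309
    phosphate_intercept: float = 0.469
    vanslyke_scale: float = 0.9287
    vanslyke_hco3_ref: float = 24.4
    vanslyke_ph_slope: float = 14.83

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0) or not math.isfinite(v):
                raise DomainError(f"constant {f.name} must be strictly positive, got {v}")


DEFAULT_CONSTANTS = AcidBaseConstants()


@dataclass
class TimepointPanel:
    """One patient's arterial blood gas and chemistry at one timepoint.

    Fields left as ``None`` are missing; operations that need them raise
    :class:`MissingDataError` naming the field.  Ca and Mg are charge
    concentrations (mEq/L of the ionized species); use
    :func:`meq_from_mmol_divalent` to convert molar values.
    """

    ph: Optional[float] = None              # unitless
    paco2: Optional[float] = None           # mmHg
    hco3_measured: Optional[float] = None   # mmol/L, analyzer-reported
    sbe_measured: Optional[float] = None    # mmol/L, analyzer-reported
    na: Optional[float] = None              # mmol/L
    k: Optional[float] = None               # mmol/L
    ca: Optional[float] = None              # mEq/L
    mg: Optional[float] = None              # mEq/L
    cl: Optional[float] = None              # mmol/L
    lactate: Optional[float] = None         # mmol/L
    albumin: Optional[float] = None         # g/L
    phosphate: Optional[float] = None       # mmol/L
    glucose: Optional[float] = None         # mg/dL
    hematocrit: Optional[float] = None      # %
    urine_ketones: Optional[int] = None     # ordinal 0..4
    urea: Optional[float] = None            # mg/dL
    creatinine: Optional[float] = None      # mg/dL

    _NONNEG = (
        "paco2", "hco3_measured", "na", "k", "ca", "mg", "cl", "lactate",
        "albumin", "phosphate", "glucose", "hematocrit", "urea", "creatinine",
    )

    def validate(self) -> "TimepointPanel":
        """Check physiological invariants on the fields that are present."""
        if self.ph is not None and not (6.5 <= self.ph <= 7.8):
            raise DomainError(f"pH {self.ph} outside [6.5, 7.8]")
        if self.paco2 is not None and not self.paco2 > 0:
            raise DomainError(f"PaCO2 must be positive, got {self.paco2}")
        for name in self._NONNEG:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative, got {v}")
        uk = self.urine_ketones
        if uk is not None and (uk != int(uk) or uk not in (0, 1, 2, 3, 4)):
            raise DomainError(f"urine_ketones must be an integer in 0..4, got {uk}")
        return self

    def require(self, *names: str, context: str = "") -> None:
        for name in names:
            if getattr(self, name) is None:
                raise MissingDataError(name, context)


def meq_from_mmol_divalent(mmol_per_l: float) -> float:
    """Charge concentration (mEq/L) of a divalent cation given mmol/L."""
    return 2.0 * mmol_per_l


def bicarbonate_from_gas(
    ph: float, paco2: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Plasma bicarbonate (mmol/L) from pH and PaCO2 via Henderson–Hasselbalch.

    ``HCO3 = alpha * PaCO2 * 10**(pH - pK)``; strictly increasing in both
    arguments.
    """
    if not paco2 > 0:
        raise DomainError(f"PaCO2 must be positive, got {paco2}")
    return constants.co2_solubility_coeff * paco2 * 10.0 ** (ph - constants.pk)


def albumin_charge(
    albumin: float, ph: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Albuminate negative-charge concentration (mmol/L), Figge linearisation.

    ``Alb[g/L] * (0.123*pH - 0.631)``, unclamped (negative at very low pH).
    """
    return albumin * (constants.albumin_slope * ph - constants.albumin_intercept)


def phosphate_charge(
    phosphate: float, ph: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Inorganic phosphate charge (mmol/L): ``Pi[mmol/L] * (0.309*pH - 0.469)``."""
    return phosphate * (constants.phosphate_slope * ph - constants.phosphate_intercept)


def apparent_strong_ion_difference(panel: TimepointPanel) -> float:
    """SIDa = Na + K + Ca + Mg − Cl − lactate (mEq/L charge balance)."""
    panel.require("na", "k", "ca", "mg", "cl", "lactate", context="SIDa")
    return panel.na + panel.k + panel.ca + panel.mg - panel.cl - panel.lactate


def strong_ion_gap(
    panel: TimepointPanel, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Strong ion gap (mmol/L): SIDa minus bicarbonate, albuminate and
    phosphate charges.

    SIG > 0 indicates unmeasured-anion acidosis (ketoanions in DKA).  The
    value is returned unclamped.
    """
    panel.require(
        "na", "k", "ca", "mg", "cl", "lactate", "ph", "paco2",
        "albumin", "phosphate", context="strong_ion_gap",
    )
    sida = apparent_strong_ion_difference(panel)
    hco3 = bicarbonate_from_gas(panel.ph, panel.paco2, constants)
    a_alb = albumin_charge(panel.albumin, panel.ph, constants)
    a_pi = phosphate_charge(panel.phosphate, panel.ph, constants)
    return sida - hco3 - a_alb - a_pi


def base_excess_chloride(
    na: float, cl: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """BE_Cl (mmol/L) = Na − Cl − 32, exactly."""
    return na - cl - constants.reference_na_cl_difference


def classify_chloremia(be_cl: float) -> str:
    """Partition BE_Cl: < 0 hyperchloremic, > 0 hypochloremic, = 0 normal."""
    if not math.isfinite(be_cl):
        raise DomainError(f"BE_Cl must be finite, got {be_cl}")
    if be_cl < 0:
        return "hyperchloremic"
    if be_cl > 0:
        return "hypochloremic"
    return "normochloremic"


def standard_base_excess(
    ph: float, paco2: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Standard base excess (mmol/L) via the Van Slyke approximation.

    ``SBE = 0.9287 * (HCO3 - 24.4 + 14.83 * (pH - 7.40))`` with HCO3 from
    :func:`bicarbonate_from_gas`.  This is a calculation convention; bedside
    analyzers report their own SBE, which the panel carries separately as
    ``sbe_measured``.
    """
    hco3 = bicarbonate_from_gas(ph, paco2, constants)
    return constants.vanslyke_scale * (
        hco3 - constants.vanslyke_hco3_ref + constants.vanslyke_ph_slope * (ph - 7.40)
    )


def hco3_from_sbe(
    sbe: float, ph: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Invert the Van Slyke relation: bicarbonate implied by an SBE at a pH."""
    return (
        sbe / constants.vanslyke_scale
        + constants.vanslyke_hco3_ref
        - constants.vanslyke_ph_slope * (ph - 7.40)
    )


def ph_from_gas(
    hco3: float, paco2: float, constants: AcidBaseConstants = DEFAULT_CONSTANTS
) -> float:
    """Henderson–Hasselbalch pH from bicarbonate and PaCO2."""
    if not (hco3 > 0 and paco2 > 0):
        raise DomainError(f"hco3 and paco2 must be positive, got {hco3}, {paco2}")
    return constants.pk + math.log10(hco3 / (constants.co2_solubility_coeff * paco2))


# Diagnostic thresholds for diabetic ketoacidosis (guideline definition).
DKA_GLUCOSE_MG_DL = 200.0   # glucose strictly above
DKA_HCO3_MMOL_L = 15.0      # bicarbonate strictly below
DKA_PH = 7.3                # pH strictly below
DKA_KETONES = 2             # urine ketones at least 2+


def is_dka(panel: TimepointPanel) -> bool:
    """Guideline DKA definition: glucose > 200 mg/dL, HCO3 < 15 mmol/L,
    pH < 7.3 and urine ketones >= 2+ — all four simultaneously.

    Inequalities on glucose/HCO3/pH are strict; the ketone threshold is
    inclusive.
    """
    panel.require("glucose", "hco3_measured", "ph", "urine_ketones", context="is_dka")
    return (
        panel.glucose > DKA_GLUCOSE_MG_DL
        and panel.hco3_measured < DKA_HCO3_MMOL_L
        and panel.ph < DKA_PH
        and panel.urine_ketones >= DKA_KETONES
    )
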
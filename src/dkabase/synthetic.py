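"""Synthetic two-arm DKA cohort generator.

No public patient-level dataset exists for this analysis, so the package
ships a generator that emulates the study conditions: admission chemistry of
adult DKA (severe metabolic acidosis, high strong ion gap from ketoanions,
respiratory compensation), two fluid regimens — a chloride-rich arm (GI,
fluids with per-litre Na−Cl difference 0, mainly 0.9% NaCl) and a balanced
arm (GII, fluids with regimen Na−Cl difference > 32 mmol) — and a six-hour
evolution driven by a single-compartment electrolyte mass balance:

* chloride and sodium at 6 h are volume-of-distribution-diluted mixes of the
  admission plasma content and the retained fraction of the infused load;
* the strong ion gap decays exponentially (ketoanion clearance under
  insulin);
* the standard base excess moves by the change in base-excess chloride, the
  cleared unmeasured-anion load and any bicarbonate bolus;
* PaCO2 follows the expected respiratory compensation for metabolic acidosis
  (Winter's relation, PaCO2 ≈ 1.5·HCO3 + 8), preserving each patient's
  admission deviation from that relation, and pH closes the system through
  Henderson–Hasselbalch.

The ICU length of stay is linear in the 6-hour chloride and lactate deltas
plus noise, so regression-recovery tests have a known ground truth.  The
evolution model is a construction of this package — a minimal mechanism that
reproduces the qualitative six-hour pattern (higher chloride, lower BE_Cl,
pH and PaCO2 in the chloride-rich arm; similar Na and SIG) — not a fitted
physiological model; every constant is configurable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import acid_base as ab
from .acid_base import AcidBaseConstants, DEFAULT_CONSTANTS, TimepointPanel
from .cohort import ADMISSION, H6, H24, CohortTable, PatientRecord, build_table
from .errors import ConfigError, SimulationError
from .fluids import (
    FluidAdministration,
    FluidRegistry,
    classify_regimen,
    electrolyte_load,
)

__all__ = ["SyntheticCohortConfig", "draw_admission_panel", "assign_regimen",
           "evolve_six_hours", "generate_cohort"]


@dataclass
class SyntheticCohortConfig:
    """All knobs of the generator, with the study-condition defaults.

    Admission distributions target the observed cohort (pH 7.10 ± 0.10,
    Cl 106 ± 7 implied via the SIG solve, SIG ~ 19 ± 6 mmol/L, glucose in the
    400–550 mg/dL range); arm sizes default to 22 (GI) and 13 (GII).
    """

    # cohort shape
    n_gi: int = 22
    n_gii: int = 13
    seed: int = 0

    # demographics
    age_mean: float = 51.0
    age_sd: float = 21.0
    p_male: float = 0.42
    bmi_mean: float = 25.0
    bmi_sd: float = 4.5
    height_mean_m: float = 1.70
    height_sd_m: float = 0.08

    # admission panel distributions
    ph_mean: float = 7.10
    ph_sd: float = 0.10
    paco2_mean: float = 16.5
    paco2_sd: float = 6.0
    paco2_min: float = 6.0
    na_mean: float = 134.0
    na_sd: float = 6.0
    k_mean: float = 4.3
    k_sd: float = 0.8
    ca_meq_mean: float = 4.6
    ca_meq_sd: float = 0.4
    mg_meq_mean: float = 1.6
    mg_meq_sd: float = 0.2
    lactate_median: float = 2.1
    lactate_log_sd: float = 0.5
    albumin_mean: float = 38.0
    albumin_sd: float = 5.0
    phosphate_mean: float = 1.2
    phosphate_sd: float = 0.3
    glucose_mean: float = 480.0
    glucose_sd: float = 130.0
    glucose_min: float = 150.0
    hct_mean: float = 40.0
    hct_sd: float = 3.0
    urea_median: float = 58.0
    urea_log_sd: float = 0.5
    creatinine_median: float = 1.6
    creatinine_log_sd: float = 0.4
    ketone_probs: Tuple[float, float, float] = (0.40, 0.35, 0.25)  # P(2+,3+,4+)
    sig_mean: float = 19.0
    sig_sd: float = 6.0
    sig_min: float = 5.0
    hco3_min: float = 2.0  # reject analyzer-implausible bicarbonate

    # fluid regimens (volumes in mL over the first 6 h)
    gi_volume_mean: float = 2302.0
    gi_volume_sd: float = 1188.0
    gi_volume_min: float = 300.0
    gi_cofluid_prob: float = 0.30
    gi_cofluid_volume_mean: float = 700.0
    gi_cofluid_volume_sd: float = 400.0
    gii_volume_mean: float = 3300.0
    gii_volume_sd: float = 1000.0
    gii_volume_min: float = 1000.0
    gii_saline_prob: float = 0.30
    gii_saline_volume_mean: float = 500.0
    gii_saline_volume_sd: float = 300.0

    # boluses / co-therapy
    gi_nahco3_mean: float = 80.0
    gi_nahco3_sd: float = 90.0
    gii_nahco3_mean: float = 100.0
    gii_nahco3_sd: float = 50.0
    kcl_zero_prob: float = 0.6
    kcl_max_mmol: float = 75.0
    insulin_median: float = 0.08
    insulin_log_sd: float = 0.4
    urine_output_median: float = 3.0
    urine_output_log_sd: float = 0.5

    # six-hour evolution
    distribution_volume_fraction: float = 0.2   # L per kg body weight
    retained_fluid_fraction: float = 0.6        # of infused volume
    urinary_na_cl_excretion_fraction: float = 0.3  # of infused Na/Cl load
    sig_clearance_rate_per_h: float = 0.12
    winters_slope: float = 1.5
    winters_intercept: float = 8.0
    winters_noise_sd: float = 2.0               # mmHg
    paco2_floor: float = 10.0                   # mmHg
    ph_6h_floor: float = 6.8                    # survivable acidaemia bound
    ph_6h_ceiling: float = 7.7                  # alkalaemia bound
    lactate_clearance_rate_per_h: float = 0.06
    lactate_noise_log_sd: float = 0.15
    glucose_6h_fraction: float = 0.6
    glucose_noise_log_sd: float = 0.10
    k_6h_drop_mmol_l: float = 0.7               # insulin-driven potassium shift
    k_6h_noise_sd: float = 0.3

    # LOS model (days)
    los_intercept: float = 2.0
    los_beta_delta_cl: float = 0.2   # days per mmol/L of 6-h chloride rise
    los_beta_delta_lactate: float = 0.3
    los_noise_sd: float = 0.5
    los_floor: float = 1.0

    max_rejection_draws: int = 10_000

    def validate(self) -> "SyntheticCohortConfig":
        if self.n_gi < 2 or self.n_gii < 2:
            raise ConfigError("need at least 2 patients per arm")
        for name in ("distribution_volume_fraction", "retained_fluid_fraction",
                     "urinary_na_cl_excretion_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        for name in ("sig_clearance_rate_per_h", "lactate_clearance_rate_per_h",
                     "winters_noise_sd", "los_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if abs(sum(self.ketone_probs) - 1.0) > 1e-9:
            raise ConfigError("ketone_probs must sum to 1")
        if not 6.5 <= self.ph_6h_floor < self.ph_6h_ceiling <= 7.8:
            raise ConfigError("need 6.5 <= ph_6h_floor < ph_6h_ceiling <= 7.8")
        return self

    @classmethod
    def from_dict(cls, d: Dict) -> "SyntheticCohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ketone_probs" in d:
            d = {**d, "ketone_probs": tuple(d["ketone_probs"])}
        return cls(**d).validate()

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["ketone_probs"] = list(d["ketone_probs"])
        return d


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float = -math.inf, high: float = math.inf) -> float:
    """Rejection-sampled truncated normal (bounds are far from the mean in
    all uses here, so this stays cheap)."""
    for _ in range(100_000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x
    raise SimulationError(f"truncated normal ({mean}, {sd}) on [{low}, {high}] "
                          "failed to accept")


def draw_admission_panel(
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> Tuple[TimepointPanel, float]:
    """Draw one DKA admission panel; returns (panel, drawn SIG target).

    pH and PaCO2 are drawn first and bicarbonate computed from them, so the
    gas triplet is internally coherent.  Chloride is then *solved* so that
    the panel's strong ion gap equals a drawn target (normal, truncated at
    ``sig_min``): the ketoanion burden is the free parameter, chloride the
    dependent one.  Draws are rejected until the guideline DKA definition
    holds.
    """
    for _ in range(config.max_rejection_draws):
        ph = _truncnorm(rng, config.ph_mean, config.ph_sd, 6.6, 7.8)
        paco2 = _truncnorm(rng, config.paco2_mean, config.paco2_sd,
                           config.paco2_min, 60.0)
        hco3 = ab.bicarbonate_from_gas(ph, paco2, constants)
        glucose = _truncnorm(rng, config.glucose_mean, config.glucose_sd,
                             config.glucose_min, 1200.0)
        ketones = int(rng.choice((2, 3, 4), p=config.ketone_probs))
        na = rng.normal(config.na_mean, config.na_sd)
        k = _truncnorm(rng, config.k_mean, config.k_sd, 1.5, 8.0)
        ca = _truncnorm(rng, config.ca_meq_mean, config.ca_meq_sd, 2.5, 7.0)
        mg = _truncnorm(rng, config.mg_meq_mean, config.mg_meq_sd, 0.6, 3.0)
        lactate = min(config.lactate_median
                      * math.exp(rng.normal(0.0, config.lactate_log_sd)), 12.0)
        albumin = _truncnorm(rng, config.albumin_mean, config.albumin_sd, 18.0, 60.0)
        phosphate = _truncnorm(rng, config.phosphate_mean, config.phosphate_sd,
                               0.3, 3.0)
        sig_target = _truncnorm(rng, config.sig_mean, config.sig_sd,
                                config.sig_min, 45.0)
        # Solve Cl from the SIG identity:
        # SIG = (Na+K+Ca+Mg-Cl-lactate) - HCO3 - A_alb - A_pi
        cl = (na + k + ca + mg - lactate
              - hco3
              - ab.albumin_charge(albumin, ph, constants)
              - ab.phosphate_charge(phosphate, ph, constants)
              - sig_target)
        if not (70.0 <= cl <= 140.0):
            continue
        if not (config.hco3_min <= hco3 < ab.DKA_HCO3_MMOL_L):
            continue
        if not (glucose > ab.DKA_GLUCOSE_MG_DL and ph < ab.DKA_PH):
            continue
        panel = TimepointPanel(
            ph=ph, paco2=paco2, hco3_measured=hco3,
            sbe_measured=ab.standard_base_excess(ph, paco2, constants),
            na=na, k=k, ca=ca, mg=mg, cl=cl, lactate=lactate,
            albumin=albumin, phosphate=phosphate, glucose=glucose,
            hematocrit=_truncnorm(rng, config.hct_mean, config.hct_sd, 20.0, 60.0),
            urine_ketones=ketones,
            urea=config.urea_median * math.exp(rng.normal(0, config.urea_log_sd)),
            creatinine=config.creatinine_median
            * math.exp(rng.normal(0, config.creatinine_log_sd)),
        ).validate()
        if ab.is_dka(panel):
            return panel, sig_target
    raise SimulationError(
        "admission-panel rejection sampling exceeded "
        f"{config.max_rejection_draws} draws: config infeasible")


_GI_COFLUIDS = ("dextrose5", "nacl_0.45", "dextrose5_nacl_0.45")
_GII_MAIN_FLUIDS = ("half_saline_bicarb", "isolyte", "isolyte_s")


def assign_regimen(
    arm: str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    patient_id: str = "",
    registry: Optional[FluidRegistry] = None,
) -> List[FluidAdministration]:
    """Draw a first-6-h fluid regimen for one patient in one arm.

    GI gets 0.9% NaCl (volume ~ N(2302, 1188) mL truncated above 300 mL)
    plus, occasionally, a second zero-difference fluid.  GII gets one of the
    three balanced/compounded fluids plus, occasionally, some 0.9% NaCl.
    The draw is rejected until the regimen classifies into its own arm.
    """
    if arm not in ("GI", "GII"):
        raise ConfigError(f"arm must be 'GI' or 'GII', got {arm!r}")
    registry = registry or FluidRegistry.default()
    for _ in range(1000):
        admins: List[FluidAdministration] = []
        if arm == "GI":
            v = _truncnorm(rng, config.gi_volume_mean, config.gi_volume_sd,
                           config.gi_volume_min, 12_000.0)
            admins.append(FluidAdministration(patient_id, "nacl_0.9", v))
            if rng.random() < config.gi_cofluid_prob:
                co = str(rng.choice(_GI_COFLUIDS))
                cv = _truncnorm(rng, config.gi_cofluid_volume_mean,
                                config.gi_cofluid_volume_sd, 0.0, 4000.0)
                admins.append(FluidAdministration(patient_id, co, cv))
        else:
            main = str(rng.choice(_GII_MAIN_FLUIDS))
            v = _truncnorm(rng, config.gii_volume_mean, config.gii_volume_sd,
                           config.gii_volume_min, 12_000.0)
            admins.append(FluidAdministration(patient_id, main, v))
            if rng.random() < config.gii_saline_prob:
                sv = _truncnorm(rng, config.gii_saline_volume_mean,
                                config.gii_saline_volume_sd, 0.0, 3000.0)
                admins.append(FluidAdministration(patient_id, "nacl_0.9", sv))
        if classify_regimen(electrolyte_load(admins, registry)) == arm:
            return admins
    raise SimulationError(f"could not draw a {arm} regimen in 1000 attempts")


def evolve_six_hours(
    panel0: TimepointPanel,
    regimen: List[FluidAdministration],
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    weight_kg: float,
    nahco3_bolus_mmol: float = 0.0,
    registry: Optional[FluidRegistry] = None,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> Tuple[TimepointPanel, Dict[str, float]]:
    """Single-compartment 6-hour evolution of an admission panel.

    Mass balance with distribution volume ``V = fraction × weight``:
    a fraction of the infused Na/Cl load is excreted, the rest mixes into
    ``V`` plus the retained infused volume; the strong ion gap decays
    exponentially; SBE moves by the BE_Cl change, the cleared SIG and the
    bicarbonate bolus; PaCO2 follows Winter's compensation offset by the
    patient's admission deviation from it; pH closes the gas system.  With
    zero infusion, zero clearance and zero noise the panel is a fixed point.

    Returns the 6th-hour panel and a diagnostics dict (sig targets, SBE,
    dilution factor).
    """
    if not weight_kg > 0:
        raise SimulationError(f"non-physical weight_kg: {weight_kg}")
    registry = registry or FluidRegistry.default()
    panel0.require("ph", "paco2", "na", "k", "ca", "mg", "cl", "lactate",
                   "albumin", "phosphate", "glucose", "hematocrit",
                   context="evolve_six_hours")
    summary = electrolyte_load(regimen, registry, window="first_6h")
    v_dist = config.distribution_volume_fraction * weight_kg          # L
    v_inf = summary.total_volume_ml / 1000.0                          # L
    keep = 1.0 - config.urinary_na_cl_excretion_fraction
    denom = v_dist + config.retained_fluid_fraction * v_inf
    cl6 = (panel0.cl * v_dist + keep * summary.administered_cl_mmol) / denom
    na6 = (panel0.na * v_dist
           + keep * (summary.administered_na_mmol + nahco3_bolus_mmol)) / denom
    if cl6 <= 0 or na6 <= 0:
        raise SimulationError(
            f"negative electrolyte concentration (cl6={cl6:.2f}, na6={na6:.2f}); "
            "check urinary_na_cl_excretion_fraction / retained_fluid_fraction")
    dilution = v_dist / denom

    sig0 = ab.strong_ion_gap(panel0, constants)
    sig6 = sig0 * math.exp(-config.sig_clearance_rate_per_h * 6.0)
    becl0 = ab.base_excess_chloride(panel0.na, panel0.cl, constants)
    becl6 = ab.base_excess_chloride(na6, cl6, constants)
    sbe0 = ab.standard_base_excess(panel0.ph, panel0.paco2, constants)
    sbe6 = sbe0 + (becl6 - becl0) + (sig0 - sig6) + nahco3_bolus_mmol / v_dist

    # Respiratory side: Winter's compensation, preserving this patient's
    # admission offset from the Winter line so an unchanged metabolic state
    # maps back to the admission gas values.
    hco3_0 = ab.bicarbonate_from_gas(panel0.ph, panel0.paco2, constants)
    winter = lambda h: config.winters_slope * h + config.winters_intercept
    resp_offset = panel0.paco2 - winter(hco3_0)
    resp_noise = rng.normal(0.0, config.winters_noise_sd) \
        if config.winters_noise_sd > 0 else 0.0

    ph = panel0.ph
    for _ in range(200):
        hco3_6 = max(ab.hco3_from_sbe(sbe6, ph, constants), 0.3)
        paco2_6 = max(winter(hco3_6) + resp_offset + resp_noise,
                      config.paco2_floor)
        ph_new = ab.ph_from_gas(hco3_6, paco2_6, constants)
        if abs(ph_new - ph) < 1e-12:
            ph = ph_new
            break
        ph = ph_new
    hco3_6 = max(ab.hco3_from_sbe(sbe6, ph, constants), 0.3)
    paco2_6 = max(winter(hco3_6) + resp_offset + resp_noise, config.paco2_floor)

    # survivability clamp: extreme simulated loads can push the gas system
    # outside the physiological range; bound pH without moving it past the
    # admission value (so the zero-intervention fixed point is untouched)
    # and restore Henderson-Hasselbalch coherence at the clamped pH
    ph_lo = min(config.ph_6h_floor, panel0.ph)
    ph_hi = max(config.ph_6h_ceiling, panel0.ph)
    if not ph_lo <= ph <= ph_hi:
        ph = min(max(ph, ph_lo), ph_hi)
        hco3_6 = ab.bicarbonate_from_gas(ph, paco2_6, constants)

    lactate6 = panel0.lactate * math.exp(
        -config.lactate_clearance_rate_per_h * 6.0)
    if config.lactate_noise_log_sd > 0:
        lactate6 *= math.exp(rng.normal(0.0, config.lactate_noise_log_sd))
    glucose6 = panel0.glucose * config.glucose_6h_fraction
    if config.glucose_noise_log_sd > 0:
        glucose6 *= math.exp(rng.normal(0.0, config.glucose_noise_log_sd))
    k6 = panel0.k * dilution - config.k_6h_drop_mmol_l
    if config.k_6h_noise_sd > 0:
        k6 += rng.normal(0.0, config.k_6h_noise_sd)
    k6 = max(k6, 1.5)

    panel6 = TimepointPanel(
        ph=ph, paco2=paco2_6, hco3_measured=hco3_6,
        sbe_measured=ab.standard_base_excess(ph, paco2_6, constants),
        na=na6, k=k6,
        ca=panel0.ca * dilution, mg=panel0.mg * dilution,
        cl=cl6, lactate=lactate6,
        albumin=panel0.albumin * dilution,
        phosphate=panel0.phosphate * dilution,
        glucose=glucose6,
        hematocrit=panel0.hematocrit * dilution,
    ).validate()
    info = {
        "sig0": sig0, "sig6_target": sig6, "sbe0": sbe0, "sbe6": sbe6,
        "becl0": becl0, "becl6": becl6, "dilution": dilution,
        "v_dist_l": v_dist, "v_infused_l": v_inf,
    }
    return panel6, info


def generate_cohort(
    config: SyntheticCohortConfig,
    registry: Optional[FluidRegistry] = None,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> Tuple[CohortTable, Dict]:
    """Generate a full two-arm cohort and its ground truth.

    Fully reproducible from ``config.seed``.  The ground-truth dict records
    the generating LOS coefficients, per-patient SIG decay targets and the
    config, so downstream recovery tests can compare estimates to truth.
    """
    config.validate()
    registry = registry or FluidRegistry.default()
    rng = np.random.default_rng(config.seed)
    records: List[PatientRecord] = []
    sig_targets: Dict[str, Tuple[float, float]] = {}
    for arm, n in (("GI", config.n_gi), ("GII", config.n_gii)):
        for i in range(n):
            pid = f"{arm}-{i + 1:03d}"
            age = _truncnorm(rng, config.age_mean, config.age_sd, 19.0, 95.0)
            sex = "male" if rng.random() < config.p_male else "female"
            bmi = _truncnorm(rng, config.bmi_mean, config.bmi_sd, 16.0, 45.0)
            height = _truncnorm(rng, config.height_mean_m, config.height_sd_m,
                                1.45, 2.05)
            weight = bmi * height ** 2
            cci = int(round(_truncnorm(rng, 3.0, 2.0, 0.0, 12.0)))
            apache2 = int(round(_truncnorm(rng, 16.0, 5.0, 4.0, 40.0)))
            sofa = int(round(_truncnorm(rng, 3.0, 2.0, 0.0, 15.0)))

            panel0, sig_t = draw_admission_panel(config, rng, constants)
            admins = assign_regimen(arm, config, rng, pid, registry)
            if arm == "GI":
                nahco3 = _truncnorm(rng, config.gi_nahco3_mean,
                                    config.gi_nahco3_sd, 0.0, 400.0)
            else:
                nahco3 = _truncnorm(rng, config.gii_nahco3_mean,
                                    config.gii_nahco3_sd, 0.0, 400.0)
            kcl = 0.0 if rng.random() < config.kcl_zero_prob \
                else rng.uniform(10.0, config.kcl_max_mmol)
            insulin = config.insulin_median * math.exp(
                rng.normal(0.0, config.insulin_log_sd))
            urine = config.urine_output_median * math.exp(
                rng.normal(0.0, config.urine_output_log_sd))

            panel6, info = evolve_six_hours(
                panel0, admins, config, rng, weight, nahco3, registry, constants)
            sig_targets[pid] = (info["sig0"], info["sig6_target"])

            panel24 = TimepointPanel(
                urea=panel0.urea * rng.uniform(0.4, 0.8),
                creatinine=panel0.creatinine * rng.uniform(0.6, 0.9),
                urine_ketones=int(max(panel0.urine_ketones
                                      - rng.integers(1, 3), 0)),
            )
            delta_cl = panel6.cl - panel0.cl
            delta_lac = panel6.lactate - panel0.lactate
            los = (config.los_intercept
                   + config.los_beta_delta_cl * delta_cl
                   + config.los_beta_delta_lactate * delta_lac
                   + rng.normal(0.0, config.los_noise_sd))
            los = max(los, config.los_floor)

            records.append(PatientRecord(
                patient_id=pid, age_years=age, sex=sex, bmi_kg_m2=bmi,
                weight_kg=weight, cci=cci, apache2=apache2, sofa=sofa,
                panels={ADMISSION: panel0, H6: panel6, H24: panel24},
                administrations=admins,
                nahco3_bolus_mmol=nahco3, kcl_mmol=kcl,
                insulin_u_per_kg_h=insulin, urine_output_ml_kg_h=urine,
                los_icu_days=los,
            ))
    table = build_table(records, registry, constants)
    ground_truth = {
        "seed": config.seed,
        "n_gi": config.n_gi,
        "n_gii": config.n_gii,
        "los_model": {
            "intercept": config.los_intercept,
            "beta_delta_cl": config.los_beta_delta_cl,
            "beta_delta_lactate": config.los_beta_delta_lactate,
            "noise_sd": config.los_noise_sd,
            "floor": config.los_floor,
        },
        "sig_targets": sig_targets,
        "config": config.to_dict(),
    }
    return table, ground_truth
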
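"""Synthetic cohort generator: determinism, coherence and pattern properties."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from dkabase import (
    FluidRegistry,
    SyntheticCohortConfig,
    assign_regimen,
    compare_groups,
    correlate_with_los,
    draw_admission_panel,
    evolve_six_hours,
    generate_cohort,
    is_dka,
    strong_ion_gap,
)
from dkabase.errors import ConfigError
from dkabase.fluids import classify_regimen, electrolyte_load


def _noise_free_config(**overrides):
    """Config with every stochastic/secular 6-h term switched off."""
    base = dict(
        winters_noise_sd=0.0, sig_clearance_rate_per_h=0.0,
        lactate_clearance_rate_per_h=0.0, lactate_noise_log_sd=0.0,
        glucose_6h_fraction=1.0, glucose_noise_log_sd=0.0,
        k_6h_drop_mmol_l=0.0, k_6h_noise_sd=0.0, paco2_floor=1.0,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


class TestConfig:
    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="not_a_knob"):
            SyntheticCohortConfig.from_dict({"not_a_knob": 1})

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticCohortConfig(retained_fluid_fraction=1.5).validate()

    def test_round_trip_dict(self):
        cfg = SyntheticCohortConfig(seed=9, n_gi=5)
        assert SyntheticCohortConfig.from_dict(cfg.to_dict()) == cfg


class TestAdmissionPanels:
    def test_all_panels_meet_dka_definition(self):
        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(0)
        for _ in range(200):
            panel, _ = draw_admission_panel(cfg, rng)
            assert is_dka(panel)

    def test_sig_matches_drawn_target(self):
        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(1)
        for _ in range(100):
            panel, target = draw_admission_panel(cfg, rng)
            assert strong_ion_gap(panel) == pytest.approx(target, abs=1e-6)

    def test_mean_ph_calibrated(self):
        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(2)
        phs = [draw_admission_panel(cfg, rng)[0].ph for _ in range(1000)]
        assert abs(np.mean(phs) - cfg.ph_mean) < 0.02


class TestRegimens:
    def test_gi_difference_exactly_zero(self, registry):
        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(3)
        for _ in range(100):
            admins = assign_regimen("GI", cfg, rng, "p")
            s = electrolyte_load(admins, registry)
            assert s.na_cl_difference_mmol == 0
            assert classify_regimen(s) == "GI"

    def test_gii_difference_above_threshold(self, registry):
        cfg = SyntheticCohortConfig()
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(500):
            admins = assign_regimen("GII", cfg, rng, "p")
            s = electrolyte_load(admins, registry)
            assert s.na_cl_difference_mmol > 32
            diffs.append(s.na_cl_difference_mmol)
        assert 95 <= np.median(diffs) <= 263

    def test_unknown_arm_rejected(self):
        with pytest.raises(ConfigError):
            assign_regimen("GIII", SyntheticCohortConfig(), np.random.default_rng(0))


class TestEvolution:
    def test_no_intervention_is_fixed_point(self):
        cfg = _noise_free_config()
        rng = np.random.default_rng(5)
        panel0, _ = draw_admission_panel(cfg, rng)
        panel6, info = evolve_six_hours(panel0, [], cfg, rng, weight_kg=70.0,
                                        nahco3_bolus_mmol=0.0)
        for f in ("ph", "paco2", "na", "cl", "k", "lactate", "glucose",
                  "hematocrit", "albumin", "phosphate", "ca", "mg"):
            assert getattr(panel6, f) == pytest.approx(
                getattr(panel0, f), abs=1e-9), f

    def test_saline_more_chloremic_than_balanced(self, registry):
        # same patient, same volume: 0.9% NaCl must raise Cl and depress
        # BE_Cl relative to the balanced fluid
        cfg = _noise_free_config()
        rng = np.random.default_rng(6)
        panel0, _ = draw_admission_panel(cfg, rng)
        from dkabase import FluidAdministration
        saline = [FluidAdministration("p", "nacl_0.9", 3000)]
        balanced = [FluidAdministration("p", "isolyte", 3000)]
        p_sal, i_sal = evolve_six_hours(copy.deepcopy(panel0), saline, cfg,
                                        np.random.default_rng(7), 70.0)
        p_bal, i_bal = evolve_six_hours(copy.deepcopy(panel0), balanced, cfg,
                                        np.random.default_rng(7), 70.0)
        assert p_sal.cl > p_bal.cl
        assert i_sal["becl6"] < i_bal["becl6"]

    def test_sig_strict_decay(self):
        cfg = SyntheticCohortConfig()
        _, gt = generate_cohort(SyntheticCohortConfig(seed=12, n_gi=30, n_gii=30))
        for sig0, sig6 in gt["sig_targets"].values():
            assert sig6 < sig0

    def test_delta_becl_is_delta_na_minus_delta_cl(self, default_cohort):
        table, _ = default_cohort
        df = table.df
        np.testing.assert_allclose(
            df["delta_becl"], df["delta_na"] - df["delta_cl"], atol=1e-12)

    def test_full_excretion_leaves_dilution_only_effect(self):
        # with every infused Na/Cl millimole excreted, the 6-h chloride must
        # equal the pure volume-dilution prediction, and the between-arm
        # contrast driven by chloride load disappears
        cfg = SyntheticCohortConfig(seed=13, n_gi=150, n_gii=150,
                                    urinary_na_cl_excretion_fraction=1.0)
        table, _ = generate_cohort(cfg)
        df = table.df
        v = cfg.distribution_volume_fraction * df["weight_kg"]
        denom = v + cfg.retained_fluid_fraction * df["fluid_volume_ml_6h"] / 1000
        np.testing.assert_allclose(df["cl_h6"], df["cl_adm"] * v / denom,
                                   rtol=1e-12)
        # the arm contrast shrinks toward the residual volume-dilution
        # difference (the chloride-poor arm receives more fluid on average,
        # so a dilution-only gap remains)
        def _gap(frame):
            m = frame.groupby("group_label")["delta_cl"].median()
            return m["GI"] - m["GII"]
        default_df = generate_cohort(SyntheticCohortConfig(
            seed=13, n_gi=150, n_gii=150))[0].df
        assert _gap(df) < _gap(default_df)


class TestGenerateCohort:
    def test_same_seed_identical_output(self):
        cfg = SyntheticCohortConfig(seed=21)
        t1, g1 = generate_cohort(cfg)
        t2, g2 = generate_cohort(SyntheticCohortConfig(seed=21))
        pd.testing.assert_frame_equal(t1.df, t2.df)
        assert g1["sig_targets"] == g2["sig_targets"]

    def test_different_seed_differs(self):
        t1, _ = generate_cohort(SyntheticCohortConfig(seed=21))
        t2, _ = generate_cohort(SyntheticCohortConfig(seed=22))
        assert not t1.df["cl_h6"].equals(t2.df["cl_h6"])

    def test_arm_sizes_and_labels(self, default_cohort):
        table, gt = default_cohort
        counts = table.df["group_label"].value_counts()
        assert counts["GI"] == gt["n_gi"] == 22
        assert counts["GII"] == gt["n_gii"] == 13

    def test_six_hour_direction_small_sweep(self):
        # the full 20-seed sweep lives in the acceptance suite
        for seed in (30, 31, 32):
            table, _ = generate_cohort(
                SyntheticCohortConfig(seed=seed, n_gi=200, n_gii=200))
            m = table.df.groupby("group_label")[
                ["cl_h6", "becl_h6", "ph_h6", "paco2_h6"]].median()
            assert m.loc["GI", "cl_h6"] > m.loc["GII", "cl_h6"]
            assert m.loc["GI", "becl_h6"] < m.loc["GII", "becl_h6"]
            assert m.loc["GI", "ph_h6"] < m.loc["GII", "ph_h6"]
            assert m.loc["GI", "paco2_h6"] < m.loc["GII", "paco2_h6"]

    def test_delta_cl_los_correlation_positive(self):
        # LOS is generated from delta-Cl with positive weight; the analysis
        # must recover the sign essentially always
        hits = 0
        for seed in range(20):
            table, _ = generate_cohort(SyntheticCohortConfig(seed=400 + seed))
            r, _ = correlate_with_los(table.df, "delta_cl")
            hits += r > 0
        assert hits >= 19

    def test_becl_h6_group_difference_detectable_in_majority_of_seeds(self):
        # at the study's own arm sizes (22 vs 13) the 6-hour BE_Cl contrast
        # should reach p < 0.05 in most replicates
        hits = sum(
            compare_groups(generate_cohort(SyntheticCohortConfig(seed=s))[0].df,
                           "becl_h6").p_value < 0.05
            for s in range(20))
        assert hits > 10
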
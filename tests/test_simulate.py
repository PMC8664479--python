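"""Synthetic dry-down generator: moisture dynamics, reaction norms,
trait derivation, and reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fvtraits.simulate import (
    ALL_TRAITS,
    TRAITS_A,
    TRAITS_B,
    DryDownDesign,
    ReactionNormSpec,
    build_plants,
    simulate_experiment,
    simulate_soil_moisture,
    simulate_trait_values,
)
from fvtraits.traits import derive_traits


class TestSoilMoisture:
    def test_no_flux_keeps_initial_moisture(self, rng):
        design = DryDownDesign(evaporation_rate=0.0, moisture_noise_sd=0.0)
        traj, final = simulate_soil_moisture(design, np.zeros(8), rng)
        assert np.allclose(final, traj[:, 0])
        assert np.allclose(final, 100.0)

    def test_treatment_means_strictly_increase_with_water(self):
        design = DryDownDesign(moisture_noise_sd=0.0)
        levels = np.asarray(design.watering_levels)
        _, final = simulate_soil_moisture(design, levels, np.random.default_rng(0))
        assert np.all(np.diff(final) > 0)

    def test_default_final_range_spans_the_prediction_grid(self):
        # the 30-100% grid used downstream must lie inside the simulated
        # final-moisture range under default parameters
        table, _ = simulate_experiment(seed=42)
        m = table["soil_moisture_final"]
        assert m.min() <= 30.0 <= m.max()
        assert m.max() >= 100.0 - 1e-9

    def test_final_distribution_is_skewed_toward_the_dry_end(self):
        table, _ = simulate_experiment(seed=42)
        m = table["soil_moisture_final"].to_numpy()
        assert stats.skew(m) > 0.05
        # more plants in the driest fifth of the realized range than in
        # the band just below the wet extreme
        lo, hi = m.min(), m.max()
        assert np.mean(m < lo + 0.2 * (hi - lo)) > np.mean(
            (m > hi - 0.2 * (hi - lo)) & (m < hi - 1e-6)
        )

    def test_as_printed_convention_offsets_by_dry_mass_ratio(self, rng):
        design = DryDownDesign(moisture_noise_sd=0.0)
        t = np.asarray(design.watering_levels)
        _, corrected = simulate_soil_moisture(design, t, rng)
        _, printed = simulate_soil_moisture(design, t, rng, as_printed=True)
        offset = design.dry_mass / design.water_capacity * 100.0
        assert np.allclose(printed - corrected, offset)
        assert printed.max() > 100.0  # the printed formula exceeds 100%

    def test_design_validation(self):
        with pytest.raises(ValueError):
            DryDownDesign(field_capacity_mass=100.0, dry_mass=200.0)
        with pytest.raises(ValueError):
            DryDownDesign(watering_levels=())
        with pytest.raises(ValueError):
            DryDownDesign(evaporation_rate=float("nan"))


class TestReactionNorms:
    def test_noise_free_generation_is_exact_function_evaluation(self, small_design):
        spec = ReactionNormSpec("y", "g", "quadratic", (1.0, 0.5, -0.002))
        m = np.linspace(30, 100, 11)
        assert np.allclose(spec(m), 1.0 + 0.5 * m - 0.002 * m**2)
        plants = build_plants(small_design)
        plants["soil_moisture_final"] = np.linspace(30, 100, len(plants))
        norms = {
            ("y", g): ReactionNormSpec("y", g, "quadratic", (1.0, 0.5, -0.002))
            for g in plants["genotype"].unique()
        }
        tab = simulate_trait_values(norms, plants, np.random.default_rng(0), split_harvest=False)
        expect = 1.0 + 0.5 * tab["soil_moisture_final"] - 0.002 * tab["soil_moisture_final"] ** 2
        assert np.array_equal(tab["y"].to_numpy(), expect.to_numpy())

    def test_coefficient_count_enforced(self):
        with pytest.raises(ValueError, match="coefficients"):
            ReactionNormSpec("y", "g", "quadratic", (1.0, 2.0))
        with pytest.raises(ValueError, match="shape"):
            ReactionNormSpec("y", "g", "cubic", (1.0,))

    def test_missing_spec_errors_with_pair_name(self, small_design):
        plants = build_plants(small_design).head(40)
        plants["soil_moisture_final"] = 50.0
        norms = {("y", "Bd01"): ReactionNormSpec("y", "Bd01", "constant", (1.0,))}
        with pytest.raises(KeyError, match="Bd02"):
            simulate_trait_values(norms, plants, np.random.default_rng(0))

    def test_replicate_means_concentrate_around_truth(self, rng):
        # CLT check: mean of noisy replicates at fixed moisture is within
        # 3 sd/sqrt(n) of the quadratic truth
        a, b, c, sd, n = 2.0, 0.3, -0.001, 1.5, 4000
        spec = ReactionNormSpec("y", "g", "quadratic", (a, b, c), (), sd)
        m = 55.0
        draws = spec(np.full(n, m)) + rng.normal(0, sd, n)
        assert abs(draws.mean() - (a + b * m + c * m * m)) < 3 * sd / np.sqrt(n)


class TestExperiment:
    def test_same_seed_reproduces_table_exactly(self):
        t1, _ = simulate_experiment(seed=9)
        t2, _ = simulate_experiment(seed=9)
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seeds_differ_only_in_stochastic_columns(self):
        t1, _ = simulate_experiment(seed=9)
        t2, _ = simulate_experiment(seed=10)
        design_cols = ["plant_id", "species", "genotype", "treatment", "cohort", "harvest_group"]
        pd.testing.assert_frame_equal(t1[design_cols], t2[design_cols])
        assert not np.allclose(t1["soil_moisture_final"], t2["soil_moisture_final"])

    def test_harvest_split_masks_trait_groups(self):
        table, _ = simulate_experiment(seed=1)
        a = table[table["harvest_group"] == "A"]
        b = table[table["harvest_group"] == "B"]
        assert a[TRAITS_A].notna().all().all() and a[TRAITS_B].isna().all().all()
        assert b[TRAITS_B].notna().all().all() and b[TRAITS_A].isna().all().all()
        full, _ = simulate_experiment(seed=1, split_harvest=False)
        assert full[ALL_TRAITS].notna().all().all()

    def test_identical_specs_give_identical_noise_free_genotypes(self, small_design):
        plants = build_plants(small_design)
        plants = plants[plants["species"] == "B_distachyon"].reset_index(drop=True)
        plants["soil_moisture_final"] = np.tile(
            np.linspace(30, 100, 24), len(plants) // 24
        )
        norms = {
            ("y", g): ReactionNormSpec("y", g, "quadratic", (1.0, 0.1, -0.001))
            for g in plants["genotype"].unique()
        }
        tab = simulate_trait_values(norms, plants, np.random.default_rng(3), split_harvest=False)
        by_geno = tab.groupby("genotype").apply(
            lambda s: s.sort_values("soil_moisture_final")["y"].to_numpy(),
            include_groups=False,
        )
        ref = by_geno.iloc[0]
        for other in by_geno.iloc[1:]:
            assert np.array_equal(ref, other)


class TestDeriveTraits:
    def test_formula_substitutions(self):
        raw = pd.DataFrame(
            {
                "mass_fresh": [1.0, 0.9, 0.5],
                "mass_turgid": [1.0, 1.0, 0.6],
                "mass_dry_leaf": [0.4, 0.5, 0.015],
                "leaf_area": [300.0, 300.0, 300.0],
                "shoot_mass": [0.2, 0.1, 0.1],
                "root_mass": [0.1, 0.05, 0.1],
                "C_content": [40.0, 42.0, 40.0],
                "N_content": [4.0, 3.0, 4.0],
            }
        )
        out = derive_traits(raw)
        assert out["RWC"].iloc[0] == pytest.approx(1.0)  # fully hydrated
        assert out["RWC"].iloc[1] == pytest.approx(0.8)
        assert out["SLA"].iloc[2] == pytest.approx(20000.0)  # 300 mm2 / 0.015 g
        assert out["root_shoot"].iloc[0] == pytest.approx(0.5)
        assert out["biomass"].iloc[1] == pytest.approx(0.15)
        assert out["C_N"].iloc[0] == pytest.approx(10.0)

    def test_undefined_ratios_flagged_missing(self):
        raw = pd.DataFrame(
            {
                "mass_fresh": [0.5],
                "mass_turgid": [0.5],
                "mass_dry_leaf": [0.5],  # turgid == dry -> RWC undefined
                "leaf_area": [200.0],
                "shoot_mass": [0.0],  # root:shoot undefined
                "root_mass": [0.1],
                "C_content": [40.0],
                "N_content": [0.0],  # C:N undefined
            }
        )
        out = derive_traits(raw)
        assert np.isnan(out["RWC"].iloc[0])
        assert np.isnan(out["root_shoot"].iloc[0])
        assert np.isnan(out["C_N"].iloc[0])

    def test_mass_ordering_violation_raises(self):
        raw = pd.DataFrame(
            {"mass_fresh": [1.2], "mass_turgid": [1.0], "mass_dry_leaf": [0.4]}
        )
        with pytest.raises(ValueError, match="ordering"):
            derive_traits(raw)
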
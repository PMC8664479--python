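import numpy as np
import pandas as pd
import pytest

from fvtraits.simulate import (
    DryDownDesign,
    ReactionNormSpec,
    build_plants,
    simulate_soil_moisture,
    simulate_trait_values,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_design():
    """Light-weight design used by fitting tests: one species' worth of
    plants is 5 genotypes x 24 = 120 rows."""
    return DryDownDesign(n_plants_per_genotype=24)


def make_species_table(
    design: DryDownDesign,
    seed: int,
    norm_builder,
    species: str = "B_distachyon",
    residual_sd: float = 1.0,
    split_harvest: bool = False,
) -> pd.DataFrame:
    """One-species plant table with trait 'y' generated by norm_builder.

    norm_builder(genotypes, rng) -> {("y", g): ReactionNormSpec}.
    """
    ss = np.random.SeedSequence(seed)
    r_m, r_t, r_n = (np.random.default_rng(s) for s in ss.spawn(3))
    plants = build_plants(design)
    plants = plants[plants["species"] == species].reset_index(drop=True)
    _, final = simulate_soil_moisture(design, plants["treatment"].to_numpy(), r_m)
    plants["soil_moisture_final"] = final
    genotypes = sorted(plants["genotype"].unique())
    norms = norm_builder(genotypes, r_n)
    return simulate_trait_values(norms, plants, r_t, split_harvest=split_harvest)


def constant_norms(genotypes, rng, base=10.0, spread=0.5, residual_sd=1.0):
    """Intercept + genotype truth: no environmental response."""
    return {
        ("y", g): ReactionNormSpec("y", g, "constant", (base + spread * i,), (), residual_sd)
        for i, g in enumerate(genotypes)
    }


def quadratic_gxe_norms(genotypes, rng, residual_sd=1.0, curvature_sd=2.0):
    """Quadratic truths with between-genotype curvature differences
    (curvature effect scaled so its trait-unit spread across the
    moisture range has sd curvature_sd)."""
    cg = rng.normal(0.0, curvature_sd, len(genotypes)) / 35.0**2
    return {
        ("y", g): ReactionNormSpec(
            "y",
            g,
            "quadratic",
            (10.0 + cg[i] * 65.0**2, 0.02 - 2.0 * cg[i] * 65.0, cg[i]),
            (),
            residual_sd,
        )
        for i, g in enumerate(genotypes)
    }
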
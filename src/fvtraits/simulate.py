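"""Synthetic dry-down experiments.

The generator emulates the structure of a greenhouse dry-down study:
two grass species with five inbred genotypes each, six daily watering
treatments (0--20 ml/day) applied for 14 days to pots starting at field
capacity, five harvest cohorts, and a destructive two-way harvest split
(half the plants yield biomass/leaf-chemistry traits, the other half
SLA and RWC).  Water input and evaporative loss produce a continuous
gradient of final gravimetric soil moisture with more plants near the
dry extreme, and each genotype expresses every trait as its own
(possibly nonlinear) function of final moisture plus cohort offsets and
residual noise.

Soil-moisture dynamics
----------------------
Pot water mass w follows, per day,

    u    = max(w - w_r, 0) / (W - w_r)          (plant-available fraction)
    w <- w - rate * W * u^p * (1 + eps)         (evapotranspiration)
    w <- min(w + input, W)                      (morning watering; pot drains)

with W the water mass at field capacity, w_r a residual fraction of W
below which water is too tightly bound to evaporate, and
eps ~ N(0, moisture_noise_sd) a daily relative perturbation of the
loss.  At field capacity the daily loss equals rate * W, which at the
defaults equals the largest water input, so the wettest treatment stays
pinned at 100%; the unwatered treatment decays to just under 30%
(slightly above the residual fraction) by day 14; and with p < 1 the
loss stays high until the soil is nearly dry, so the intermediate
treatments' equilibria crowd toward the dry end, reproducing the
characteristic dry-skewed pooled distribution of final moisture.
Gravimetric moisture is reported
as (mass_d - mass_dry) / (mass_max - mass_dry) * 100 by default; the
``as_printed`` flag instead computes mass_d / (mass_max - mass_dry),
a convention that includes the dry soil mass in the numerator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

#: traits measured on the biomass/chemistry half of the harvest (group A)
TRAITS_A = [
    "green_area",
    "shoot_mass",
    "root_mass",
    "root_shoot",
    "biomass",
    "C_content",
    "d13C",
    "N_content",
    "d15N",
    "C_N",
]
#: traits measured on the water-relations half of the harvest (group B)
TRAITS_B = ["SLA", "RWC"]
ALL_TRAITS = ["RWC", "SLA"] + TRAITS_A

SPECIES = ("B_distachyon", "B_sylvaticum")

#: knot of the 'spline_like' truncated-cubic hinge, % gravimetric moisture
HINGE_KNOT = 65.0


@dataclass(frozen=True)
class DryDownDesign:
    """Experimental design of a synthetic dry-down."""

    n_genotypes_per_species: int = 5
    n_plants_per_genotype: int = 60
    watering_levels: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_days: int = 14
    n_cohorts: int = 5
    field_capacity_mass: float = 600.0  # grams, pot + soil + water at capacity
    dry_mass: float = 400.0  # grams, pot + dry soil
    evaporation_rate: float = 0.10  # fraction of capacity water lost per day at capacity
    drying_exponent: float = 0.5  # moisture dependence of the daily loss
    residual_moisture: float = 0.28  # bound-water fraction of capacity; no loss below it
    moisture_noise_sd: float = 0.2  # sd of the relative daily-loss perturbation

    def __post_init__(self) -> None:
        vals = [
            self.n_days,
            self.n_cohorts,
            self.field_capacity_mass,
            self.dry_mass,
            self.evaporation_rate,
            self.drying_exponent,
            self.residual_moisture,
            self.moisture_noise_sd,
            *self.watering_levels,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("design parameters must be finite")
        if not self.watering_levels or min(self.watering_levels) < 0:
            raise ValueError("watering_levels must be non-empty and non-negative")
        if self.n_days < 1 or self.n_cohorts < 1:
            raise ValueError("n_days and n_cohorts must be >= 1")
        if not self.field_capacity_mass > self.dry_mass:
            raise ValueError("field_capacity_mass must exceed dry_mass")
        if self.evaporation_rate < 0 or self.moisture_noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")
        if not 0 <= self.residual_moisture < 1:
            raise ValueError("residual_moisture must be in [0, 1)")

    @property
    def water_capacity(self) -> float:
        return self.field_capacity_mass - self.dry_mass


def simulate_soil_moisture(
    design: DryDownDesign,
    treatments: np.ndarray,
    rng: np.random.Generator,
    as_printed: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Daily morning soil-moisture trajectories for one pot per row.

    Returns (trajectory, final): trajectory has n_days+1 columns (day 0
    at field capacity, then each morning's measurement after watering);
    final is the day-``n_days`` morning value, clipped positive.
    """
    treatments = np.asarray(treatments, float)
    n = treatments.size
    W = design.water_capacity
    w = np.full(n, W)
    floor = 1e-9 * W

    def gravimetric(water: np.ndarray) -> np.ndarray:
        mass_d = water if not as_printed else water + design.dry_mass
        return mass_d / W * 100.0

    w_r = design.residual_moisture * W
    traj = np.empty((n, design.n_days + 1))
    traj[:, 0] = gravimetric(w)
    for d in range(1, design.n_days + 1):
        avail = np.clip((w - w_r) / (W - w_r), 0.0, None)
        loss = design.evaporation_rate * W * avail**design.drying_exponent
        eps = (
            rng.normal(0.0, design.moisture_noise_sd, n)
            if design.moisture_noise_sd > 0
            else np.zeros(n)
        )
        w = np.clip(w - loss * (1.0 + eps), floor, None)
        w = np.minimum(w + treatments, W)  # morning watering; excess drains
        traj[:, d] = gravimetric(w)
    return traj, traj[:, -1].copy()


@dataclass(frozen=True)
class ReactionNormSpec:
    """Generative reaction norm for one (trait, genotype) pair.

    Shapes: constant [a]; linear [a, b]; quadratic [a, b, c];
    spline_like [a, b, c, d] = quadratic plus a truncated cubic hinge
    d * max(m - 65, 0)^3, a smooth piecewise shape a quadratic cannot
    represent.
    """

    trait: str
    genotype: str
    shape: str
    coefficients: tuple[float, ...]
    cohort_effects: tuple[float, ...] = ()
    residual_sd: float = 0.0

    _NCOEF = {"constant": 1, "linear": 2, "quadratic": 3, "spline_like": 4}

    def __post_init__(self) -> None:
        if self.shape not in self._NCOEF:
            raise ValueError(f"unknown shape {self.shape!r}")
        if len(self.coefficients) != self._NCOEF[self.shape]:
            raise ValueError(
                f"shape {self.shape!r} needs {self._NCOEF[self.shape]} coefficients,"
                f" got {len(self.coefficients)}"
            )
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    def __call__(self, m) -> np.ndarray:
        """True genotype mean as a function of soil moisture (no noise,
        no cohort effect)."""
        m = np.asarray(m, float)
        c = self.coefficients
        out = np.full_like(m, c[0], dtype=float)
        if len(c) > 1:
            out = out + c[1] * m
        if len(c) > 2:
            out = out + c[2] * m**2
        if len(c) > 3:
            out = out + c[3] * np.clip(m - HINGE_KNOT, 0.0, None) ** 3
        return out


def simulate_trait_values(
    norms: dict[tuple[str, str], ReactionNormSpec],
    plants: pd.DataFrame,
    rng: np.random.Generator,
    split_harvest: bool = True,
) -> pd.DataFrame:
    """Fill trait columns of a plant table from reaction-norm specs.

    value = f_genotype(moisture) + cohort_effect + N(0, residual_sd).
    With `split_harvest`, group A plants carry only the biomass and
    leaf-chemistry traits and group B plants only SLA and RWC.
    """
    table = plants.copy()
    traits = sorted({t for t, _ in norms})
    m = table["soil_moisture_final"].to_numpy(float)
    cohort_idx = table["cohort"].to_numpy(int) - 1
    for trait in traits:
        values = np.full(len(table), np.nan)
        for genotype, idx in table.groupby("genotype", sort=True).indices.items():
            key = (trait, str(genotype))
            if key not in norms:
                raise KeyError(f"no reaction-norm spec for trait/genotype {key}")
            spec = norms[key]
            v = spec(m[idx])
            if spec.cohort_effects:
                v = v + np.asarray(spec.cohort_effects)[cohort_idx[idx]]
            if spec.residual_sd > 0:
                v = v + rng.normal(0.0, spec.residual_sd, idx.size)
            values[idx] = v
        if split_harvest:
            grp = table["harvest_group"].to_numpy()
            if trait in TRAITS_A:
                values[grp != "A"] = np.nan
            elif trait in TRAITS_B:
                values[grp != "B"] = np.nan
        table[trait] = values
    return table


# --- default study-like generative parameters ------------------------------

#: per species: trait -> (value at 30%, value at 65%, value at 100% moisture)
#: shapes chosen to echo the qualitative responses of a dry-down study:
#: RWC and green area fall toward dry soil, SLA peaks at intermediate
#: moisture in the annual, root:shoot rises under drought, d13C (WUE proxy)
#: is least negative in dry soil and higher overall in the perennial.
TRAIT_ANCHORS: dict[str, dict[str, tuple[float, float, float]]] = {
    "B_distachyon": {
        "RWC": (0.870, 0.970, 0.980),
        "SLA": (14000.0, 21000.0, 19000.0),
        "green_area": (20000.0, 80000.0, 100000.0),
        "shoot_mass": (0.05, 0.20, 0.25),
        "root_mass": (0.04, 0.13, 0.15),
        "root_shoot": (0.80, 0.62, 0.58),
        "biomass": (0.09, 0.33, 0.40),
        "C_content": (41.0, 42.0, 42.5),
        "d13C": (-27.5, -29.5, -30.5),
        "N_content": (2.5, 3.2, 3.5),
        "d15N": (1.5, 2.2, 2.5),
        "C_N": (16.4, 13.1, 12.1),
    },
    "B_sylvaticum": {
        "RWC": (0.870, 0.965, 0.975),
        "SLA": (18000.0, 19200.0, 18600.0),
        "green_area": (30000.0, 70000.0, 90000.0),
        "shoot_mass": (0.08, 0.22, 0.28),
        "root_mass": (0.120, 0.126, 0.130),
        "root_shoot": (0.75, 0.60, 0.55),
        "biomass": (0.33, 0.35, 0.36),
        "C_content": (40.0, 41.5, 42.0),
        "d13C": (-26.0, -28.0, -29.0),
        "N_content": (4.2, 3.1, 3.4),
        "d15N": (1.0, 1.8, 2.2),
        "C_N": (9.5, 13.4, 12.4),
    },
}

#: traits with genotype-by-environment curvature variation, per species
GXE_TRAITS = {
    "B_distachyon": {"SLA", "root_mass"},
    "B_sylvaticum": {"RWC", "green_area", "N_content", "C_N", "root_shoot"},
}

#: traits with essentially no genotype-level signal (so some selected
#: models omit G, as happens for a few trait/species pairs in practice)
NO_GENOTYPE_TRAITS = {
    "B_distachyon": {"RWC", "C_content"},
    "B_sylvaticum": {"d15N"},
}

#: per-trait relative sd of genotype intercepts: size-like traits vary
#: substantially between inbred lines, composition and hydration traits
#: only by a few percent
TRAIT_GENOTYPE_CV = {
    "RWC": 0.02,
    "SLA": 0.08,
    "green_area": 0.16,
    "shoot_mass": 0.16,
    "root_mass": 0.16,
    "root_shoot": 0.08,
    "biomass": 0.16,
    "C_content": 0.015,
    "d13C": 0.012,
    "N_content": 0.08,
    "d15N": 0.10,
    "C_N": 0.08,
}
#: the shared 'quality' factor dominates the idiosyncratic part so that
#: genetic covariance among traits concentrates on one axis (nD near 1),
#: as is typical when overall vigor drives most traits
IDIO_FRACTION = 0.1  # genotype x trait idiosyncrasy relative to the shared factor

#: moisture profile of genotype-effect amplitude, (value at 30%, value at
#: 100%), linear in between: the annual expresses most genetic variation
#: under drought, the perennial under wet conditions — the contrasting
#: cryptic-variation pattern expected from their life histories
GENOTYPE_AMPLITUDE = {
    "B_distachyon": (1.4, 0.6),
    "B_sylvaticum": (0.5, 1.5),
}
GXE_SD = 0.12  # curvature spread as a fraction of the trait's env range
GXE_QUALITY_CORR = 0.9  # correlation of GxE curvature with the shared factor
RESIDUAL_CV = 0.05
COHORT_STEP = 0.012  # additive cohort offset per day of age, x trait scale


def _quadratic_through(v30: float, v65: float, v100: float) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the parabola through the three anchors."""
    A = np.array([[1.0, m, m * m] for m in (30.0, 65.0, 100.0)])
    a, b, c = np.linalg.solve(A, np.array([v30, v65, v100]))
    return float(a), float(b), float(c)


def default_reaction_norms(
    design: DryDownDesign, rng: np.random.Generator
) -> dict[tuple[str, str], ReactionNormSpec]:
    """Build the default generative reaction norms for every trait x
    genotype of both species.

    Genotype intercepts share a latent per-genotype 'quality' factor
    (plus a smaller idiosyncratic part), so genetic covariance among
    traits is dominated by one axis; flagged traits additionally vary in
    quadratic curvature between genotypes (GxE).
    """
    norms: dict[tuple[str, str], ReactionNormSpec] = {}
    for species in SPECIES:
        tag = "Bd" if species == "B_distachyon" else "Bs"
        genotypes = [f"{tag}{i+1:02d}" for i in range(design.n_genotypes_per_species)]
        quality = rng.normal(0.0, 1.0, len(genotypes))
        for trait, anchors in TRAIT_ANCHORS[species].items():
            a, b, c = _quadratic_through(*anchors)
            scale = abs(anchors[1])
            env_range = max(abs(anchors[2] - anchors[0]), 0.1 * scale)
            idio = rng.normal(0.0, 1.0, len(genotypes))
            curve = GXE_QUALITY_CORR * quality + np.sqrt(
                1.0 - GXE_QUALITY_CORR**2
            ) * rng.normal(0.0, 1.0, len(genotypes))
            cohort_effects = tuple(
                COHORT_STEP * scale * (j - (design.n_cohorts - 1) / 2)
                for j in range(design.n_cohorts)
            )
            for i, g in enumerate(genotypes):
                if trait in NO_GENOTYPE_TRAITS[species]:
                    shift = 0.0
                else:
                    cv = TRAIT_GENOTYPE_CV[trait]
                    shift = cv * scale * (quality[i] + IDIO_FRACTION * idio[i])
                # genotype effects scale linearly with moisture between
                # the species' dry/wet amplitudes; this is linear GxE, so
                # it folds into the quadratic's intercept and slope
                amp_dry, amp_wet = GENOTYPE_AMPLITUDE[species]
                amp_slope = (amp_wet - amp_dry) / 70.0
                amp_icept = amp_dry - 30.0 * amp_slope
                ai = a + shift * amp_icept
                bi = b + shift * amp_slope
                ci = c
                if trait in GXE_TRAITS[species]:
                    # genotype-specific curvature, anchored at the hinge knot
                    # so genotypes cross rather than just shift
                    d = GXE_SD * env_range * curve[i] / 35.0**2
                    ai += d * HINGE_KNOT**2
                    bi += -2.0 * d * HINGE_KNOT
                    ci += d
                norms[(trait, g)] = ReactionNormSpec(
                    trait=trait,
                    genotype=g,
                    shape="quadratic",
                    coefficients=(ai, bi, ci),
                    cohort_effects=cohort_effects,
                    residual_sd=RESIDUAL_CV * scale,
                )
    return norms


def build_plants(design: DryDownDesign) -> pd.DataFrame:
    """Plant-level design table (no moisture or traits yet): species,
    genotype, watering treatment, harvest cohort and harvest group are
    balanced within genotype."""
    rows = []
    pid = 0
    n_treat = len(design.watering_levels)
    for species in SPECIES:
        tag = "Bd" if species == "B_distachyon" else "Bs"
        for gi in range(design.n_genotypes_per_species):
            genotype = f"{tag}{gi+1:02d}"
            for k in range(design.n_plants_per_genotype):
                pid += 1
                rows.append(
                    {
                        "plant_id": f"P{pid:04d}",
                        "species": species,
                        "genotype": genotype,
                        "treatment": design.watering_levels[k % n_treat],
                        "cohort": (k // n_treat) % design.n_cohorts + 1,
                        # alternate within and across treatment blocks so both
                        # harvest groups cover every treatment
                        "harvest_group": "AB"[(k + k // n_treat) % 2],
                    }
                )
    return pd.DataFrame(rows)


def simulate_experiment(
    design: DryDownDesign | None = None,
    seed: int = 0,
    norms: dict[tuple[str, str], ReactionNormSpec] | None = None,
    split_harvest: bool = True,
    as_printed: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ReactionNormSpec]]:
    """One full synthetic experiment.

    Returns the plant-level trait table and the true generative
    reaction norms (kept for recovery tests).  All randomness flows
    from `seed`; stage streams (norm construction, moisture, traits)
    are spawned deterministically from it.
    """
    design = design or DryDownDesign()
    ss = np.random.SeedSequence(seed)
    rng_norms, rng_moisture, rng_traits = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    plants = build_plants(design)
    _, final = simulate_soil_moisture(
        design, plants["treatment"].to_numpy(), rng_moisture, as_printed=as_printed
    )
    plants["soil_moisture_final"] = np.clip(final, 1e-6, None)
    if norms is None:
        norms = default_reaction_norms(design, rng_norms)
    table = simulate_trait_values(norms, plants, rng_traits, split_harvest=split_harvest)
    return table, norms


def norms_to_records(norms: dict[tuple[str, str], ReactionNormSpec]) -> list[dict]:
    """Plain-dict form of the generative truth, for the YAML sidecar."""
    records = []
    for k in sorted(norms):
        d = asdict(norms[k])
        d["coefficients"] = [float(c) for c in d["coefficients"]]
        d["cohort_effects"] = [float(c) for c in d["cohort_effects"]]
        d["residual_sd"] = float(d["residual_sd"])
        records.append(d)
    return records
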
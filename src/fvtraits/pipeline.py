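"""End-to-end analysis pipeline and trait-table IO.

Stages: (1) per species x trait stepwise reaction-norm selection,
(2) predicted genotype means on the moisture grid, (3) genetic
correlation curves, (4) multivariate plasticity (dT, species t-tests,
PCA), (5) G-matrix constraint curves.  Every stage writes a plain CSV;
a JSON manifest records each artifact with its SHA-256 so a run is
byte-reproducible under a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constraints as cons
from . import plasticity as plas
from . import predict as pred
from .model import FULL_MODEL
from .selection import select_all, term_matrix
from .simulate import ALL_TRAITS, DryDownDesign, norms_to_records, simulate_experiment

REQUIRED_COLUMNS = ["plant_id", "species", "genotype", "cohort", "soil_moisture_final"]

FLOAT_FORMAT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CSV input or synthetic)."""

    input_csv: str | None = None
    synthetic: bool = True
    seed: int = 0
    traits: list[str] = field(default_factory=lambda: list(ALL_TRAITS))
    grid_min: float = 30.0
    grid_max: float = 100.0
    grid_n: int = 20
    spline_df: int = 2
    full_terms: list[str] | None = None  # stepwise scope; default = 8-term full model
    abs_mean_standardize: bool = False
    as_printed_moisture: bool = False
    split_harvest: bool = True
    include_no_genotype_traits_in_delta_t: bool = True
    output_dir: str = "fvt_output"
    design: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def moisture_grid(self) -> np.ndarray:
        return pred.moisture_grid(self.grid_min, self.grid_max, self.grid_n)


def read_trait_table(path: str | Path, traits: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a plant-level trait table CSV."""
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table is missing required columns: {missing}")
    traits = traits or [t for t in ALL_TRAITS if t in table.columns]
    for t in traits:
        coerced = pd.to_numeric(table[t], errors="coerce")
        bad = table.index[coerced.isna() & table[t].notna()].tolist()
        if bad:
            raise ValueError(f"non-numeric values in trait {t!r} at rows {bad}")
        table[t] = coerced
    sp_per_geno = table.groupby("genotype")["species"].nunique()
    multi = sp_per_geno[sp_per_geno > 1].index.tolist()
    if multi:
        raise ValueError(f"genotype(s) mapped to more than one species: {multi}")
    if not (table["soil_moisture_final"] > 0).all():
        raise ValueError("soil_moisture_final must be positive")
    return table


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def missingness_report(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Non-missing counts per trait x species (harvest-split audit)."""
    out = (
        table.groupby("species")[[t for t in traits if t in table]]
        .count()
        .reset_index()
        .melt(id_vars="species", var_name="trait", value_name="n_observed")
    )
    return out.sort_values(["species", "trait"]).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the artifact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        artifacts[name] = path

    # input
    if config.input_csv:
        table = read_trait_table(config.input_csv, config.traits)
        norms = None
    else:
        design = DryDownDesign(**config.design)
        table, norms = simulate_experiment(
            design,
            seed=config.seed,
            split_harvest=config.split_harvest,
            as_printed=config.as_printed_moisture,
        )
        save("trait_table.csv", table)
        with open(out / "true_norms.yaml", "w") as fh:
            yaml.safe_dump(
                {"design": vars(design) | {}, "norms": norms_to_records(norms)},
                fh,
                sort_keys=True,
            )
        artifacts["true_norms.yaml"] = out / "true_norms.yaml"
    traits = [t for t in config.traits if t in table.columns]
    save("missingness.csv", missingness_report(table, traits))

    # stage 1: model selection
    scope = FULL_MODEL if config.full_terms is None else frozenset(config.full_terms)
    models = select_all(table, traits, spline_df=config.spline_df, full=scope)
    save("model_terms.csv", term_matrix(models))
    with open(out / "models.json", "w") as fh:
        json.dump([m.record() for m in models], fh, indent=1, sort_keys=True)
    artifacts["models.json"] = out / "models.json"
    with open(out / "selection_trace.json", "w") as fh:
        json.dump(
            {f"{m.species}/{m.trait}": m.trace for m in models},
            fh,
            indent=1,
            sort_keys=True,
        )
    artifacts["selection_trace.json"] = out / "selection_trace.json"

    # stage 2: genotype means on the grid
    grid = config.moisture_grid()
    grid_means = pred.genotype_mean_grid(models, grid)
    save("genotype_means.csv", grid_means)

    # stage 3: correlation curves
    save("correlations.csv", pred.correlation_curves(grid_means, models))

    # stage 4: plasticity
    delta_frames, score_frames, load_frames, frac_frames = [], [], [], []
    for species in sorted({m.species for m in models}):
        trait_subset = [
            m.trait
            for m in models
            if m.species == species
            and (config.include_no_genotype_traits_in_delta_t or m.genotype_distinguishable)
        ]
        sub = grid_means[
            (grid_means["species"] == species) & grid_means["trait"].isin(trait_subset)
        ]
        # a trait whose model kept no terms at all is one constant value
        # over all genotypes and levels; it cannot be z-scored and adds
        # nothing to a distance, so it leaves the trait space here
        variable = sub.groupby("trait")["value"].std(ddof=1) > 0
        space = plas.scaled_trait_space(
            sub[sub["trait"].isin(variable[variable].index)], species
        )
        d = plas.delta_t(space)
        d.insert(0, "species", species)
        delta_frames.append(d)
        scores, loadings, frac = plas.trait_space_pca(space)
        s = scores.reset_index()
        s.insert(0, "species", species)
        score_frames.append(s)
        ld = loadings.reset_index(names="trait")
        ld.insert(0, "species", species)
        load_frames.append(ld)
        frac_df = frac.rename_axis("component").reset_index()
        frac_df.insert(0, "species", species)
        frac_frames.append(frac_df)
    save("pca_variance.csv", pd.concat(frac_frames, ignore_index=True))
    series = pd.concat(delta_frames, ignore_index=True)
    save("plasticity.csv", series)
    if series["species"].nunique() == 2:
        save("plasticity_tests.csv", plas.species_contrast(series))
    save("pca_scores.csv", pd.concat(score_frames, ignore_index=True))
    save("pca_loadings.csv", pd.concat(load_frames, ignore_index=True))

    # stage 5: constraint curves
    traits_by_species: dict[str, list[str]] = {}
    for m in models:
        if m.genotype_distinguishable:
            traits_by_species.setdefault(m.species, []).append(m.trait)
    save(
        "constraints.csv",
        cons.constraint_curves(
            grid_means, grid, traits_by_species, abs_mean=config.abs_mean_standardize
        ),
    )

    manifest = {
        "seed": config.seed,
        "grid": [config.grid_min, config.grid_max, config.grid_n],
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(artifacts.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
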
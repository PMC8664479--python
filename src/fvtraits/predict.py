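"""Genotype means and genetic correlations along the soil-moisture grid.

Predicted genotypic means for every trait are evaluated from the
selected reaction-norm model at 20 evenly spaced gravimetric
soil-moisture levels from 30% to 100%.  Harvest cohort is a nuisance
covariate: predictions are averaged over all cohort levels with equal
weight, which makes them invariant to the choice of reference level.
Pearson correlations between genotype means, computed per trait pair at
each level within a species, then describe how genetic correlations
move along the gradient.  Pairs are only formed between traits whose
final model distinguishes genotypes at all.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .selection import FittedTraitModel


def moisture_grid(lo: float = 30.0, hi: float = 100.0, n: int = 20) -> np.ndarray:
    """Evenly spaced soil-moisture levels, m = (m_1, ..., m_n)."""
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi and n >= 2):
        raise ValueError("grid requires lo < hi and n >= 2")
    return np.linspace(lo, hi, n)


def predict_genotype_means(
    model: FittedTraitModel, grid: np.ndarray
) -> pd.DataFrame:
    """Long-format predicted means: one row per genotype x grid level,
    with predictions averaged over harvest cohorts."""
    grid = np.asarray(grid, float)
    genotypes = model.info.genotype_levels
    cohorts = model.info.cohort_levels
    frames = []
    for g in genotypes:
        newdata = pd.DataFrame(
            {
                "genotype": np.repeat(g, grid.size * len(cohorts)),
                "cohort": np.tile(np.repeat(cohorts, grid.size), 1),
                "soil_moisture_final": np.tile(grid, len(cohorts)),
            }
        )
        pred = model.predict(newdata).reshape(len(cohorts), grid.size).mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "species": model.species,
                    "trait": model.trait,
                    "genotype": g,
                    "level": grid,
                    "value": pred,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def genotype_mean_grid(
    models: list[FittedTraitModel], grid: np.ndarray
) -> pd.DataFrame:
    """Stack predicted genotype means for a set of fitted models."""
    return pd.concat(
        [predict_genotype_means(m, grid) for m in models], ignore_index=True
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Pearson r; NaN (flagged missing) when either side is constant."""
    da = a - a.mean()
    db = b - b.mean()
    va = da @ da
    vb = db @ db
    if va <= 0 or vb <= 0:
        return np.nan
    return float((da @ db) / np.sqrt(va * vb))


def correlation_curves(
    grid_means: pd.DataFrame, models: list[FittedTraitModel] | None = None
) -> pd.DataFrame:
    """Pearson correlations of genotype means per unordered trait pair
    per level within species.

    If `models` is given, traits whose final model cannot distinguish
    genotypes are omitted (their "genetic" correlation is undefined).
    """
    keep: dict[str, set[str]] | None = None
    if models is not None:
        keep = {}
        for m in models:
            if m.genotype_distinguishable:
                keep.setdefault(m.species, set()).add(m.trait)
    rows = []
    for species, sub in grid_means.groupby("species", sort=True):
        traits = sorted(sub["trait"].unique())
        if keep is not None:
            traits = [t for t in traits if t in keep.get(species, set())]
        wide = sub.pivot_table(
            index=["genotype", "level"], columns="trait", values="value"
        )
        for ta, tb in combinations(traits, 2):
            for level, lv in wide.groupby(level="level", sort=True):
                rows.append(
                    {
                        "species": species,
                        "trait_a": ta,
                        "trait_b": tb,
                        "level": level,
                        "r": _pearson(lv[ta].to_numpy(), lv[tb].to_numpy()),
                    }
                )
    return pd.DataFrame(rows)
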
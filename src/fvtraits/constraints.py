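"""Evolutionary-constraint statistics from the genetic covariance matrix.

At each soil-moisture level the G matrix is approximated by the sample
covariance (divisor n-1) of mean-standardized genotype trait means:
each trait's predicted genotype means at that level are divided by
their mean across genotypes, so variances are comparable across traits
with different units.  From the eigenvalues l_1 >= ... >= l_n of G:

    nD   = sum(l_i) / l_1     effective number of dimensions (1..n)
    emax = sqrt(l_1)          maximum evolvability
    vT   = sum(l_i) = tr(G)   total genetic variance
    prop1 = l_1 / sum(l_i)    first-eigenvector share (= 1/nD)

nD near 1 means genetic variation is concentrated on a single axis
(strong covariance constraint); nD near n means no covariance
constraint at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: eigenvalues below -EIG_TOL * l_1 are a PSD violation; within it they clamp to 0
EIG_TOL = 1e-10
#: |trait mean| below MEAN_EPS * sd flags unstable mean standardization
MEAN_EPS = 1e-8


@dataclass
class GMatrix:
    species: str
    level: float
    matrix: np.ndarray
    traits: list[str]
    means: np.ndarray  # standardization means, one per trait

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("G matrix must be symmetric")


def g_matrix(
    grid_means: pd.DataFrame,
    species: str,
    level: float,
    traits: list[str] | None = None,
    abs_mean: bool = False,
    standardize_means: np.ndarray | None = None,
) -> GMatrix:
    """Mean-standardized genetic covariance matrix at one grid level.

    `abs_mean` divides by |mean| instead of the signed mean (relevant
    for traits with negative means such as d13C, whose standardized
    deviations otherwise flip sign).  `standardize_means` overrides the
    per-level means (e.g. with grand means across levels).
    """
    sub = grid_means[
        (grid_means["species"] == species) & (grid_means["level"] == level)
    ]
    wide = sub.pivot_table(index="genotype", columns="trait", values="value")
    if traits is not None:
        wide = wide[[t for t in traits if t in wide]]
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    X = wide.to_numpy(float)
    mu = X.mean(axis=0) if standardize_means is None else np.asarray(standardize_means, float)
    sd = X.std(axis=0, ddof=1)
    unstable = np.abs(mu) <= MEAN_EPS * np.maximum(sd, 1.0)
    if unstable.any():
        dropped = [t for t, u in zip(wide.columns, unstable) if u]
        warnings.warn(
            f"dropping trait(s) with near-zero mean at level {level}: {dropped}",
            stacklevel=2,
        )
        X, mu = X[:, ~unstable], mu[~unstable]
        wide = wide.loc[:, ~unstable]
    denom = np.abs(mu) if abs_mean else mu
    Z = X / denom
    cov = np.cov(Z, rowvar=False, ddof=1)
    return GMatrix(species, float(level), np.atleast_2d(cov), list(wide.columns), mu)


def constraint_stats(G: GMatrix) -> dict:
    """Eigen-decompose G and derive nD, emax, vT and prop1."""
    eig = np.linalg.eigvalsh(G.matrix)[::-1]
    lead = eig[0] if eig[0] > 0 else 1.0
    if eig[-1] < -EIG_TOL * lead:
        warnings.warn(
            f"G at level {G.level} has eigenvalue {eig[-1]:.3e} below -tol; clamping",
            stacklevel=2,
        )
    eig = np.clip(eig, 0.0, None)
    total = float(eig.sum())
    lam1 = float(eig[0])
    row = {
        "species": G.species,
        "level": G.level,
        "n_traits": len(G.traits),
        "vT": total,
        "emax": float(np.sqrt(lam1)),
        "nD": total / lam1 if lam1 > 0 else np.nan,
        "prop1": lam1 / total if total > 0 else np.nan,
        "eigenvalues": eig,
    }
    return row


def constraint_curves(
    grid_means: pd.DataFrame,
    levels: np.ndarray,
    traits_by_species: dict[str, list[str]] | None = None,
    abs_mean: bool = False,
) -> pd.DataFrame:
    """Constraint summary per species x level.

    `traits_by_species` restricts each species to the traits whose
    selected model distinguishes genotypes (traits without genotype
    terms carry no genetic variance and are excluded by default
    upstream).  Levels that fail are kept as flagged NaN rows.
    """
    rows = []
    for species in sorted(grid_means["species"].unique()):
        traits = None if traits_by_species is None else traits_by_species.get(species)
        for level in np.asarray(levels, float):
            try:
                row = constraint_stats(
                    g_matrix(grid_means, species, level, traits=traits, abs_mean=abs_mean)
                )
            except (ValueError, KeyError) as err:
                row = {
                    "species": species,
                    "level": level,
                    "n_traits": 0,
                    "vT": np.nan,
                    "emax": np.nan,
                    "nD": np.nan,
                    "prop1": np.nan,
                    "eigenvalues": np.array([]),
                    "error": str(err),
                }
            rows.append(row)
    out = pd.DataFrame(rows)
    out["eigenvalues"] = out["eigenvalues"].map(
        lambda e: ";".join(f"{v:.10g}" for v in np.asarray(e).ravel())
    )
    return out
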
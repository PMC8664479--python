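"""Multivariate plasticity through scaled trait space.

Each genotype traces a path through n-dimensional trait space as soil
moisture varies.  After z-scoring every trait (mean 0, sd 1, pooled over
all genotype x level predicted means within a species), total plasticity
between consecutive grid levels is the Euclidean step length

    dT_{g,i} = sqrt( sum_j (p_{g,i,j} - p_{g,i+1,j})^2 )

over the n trait dimensions, giving 19 intervals for a 20-level grid.
Species are compared per interval with Welch (unequal-variance) two
sample t-tests on genotype dT values, and the scaled trait space is
summarized by a centered PCA (sample-covariance convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


def scaled_trait_space(grid_means: pd.DataFrame, species: str) -> pd.DataFrame:
    """Genotype x level rows by trait columns, each trait z-scored over
    the pooled rows of one species; scaling constants in ``.attrs``."""
    sub = grid_means[grid_means["species"] == species]
    if sub.empty:
        raise ValueError(f"no rows for species {species!r}")
    wide = sub.pivot_table(index=["genotype", "level"], columns="trait", values="value")
    mu = wide.mean(axis=0)
    sd = wide.std(axis=0, ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise ValueError(f"constant trait(s) cannot be scaled: {constant}")
    scaled = (wide - mu) / sd
    scaled.attrs["mean"] = mu
    scaled.attrs["sd"] = sd
    return scaled


def unscale(space: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`scaled_trait_space` using the stored constants."""
    return space * space.attrs["sd"] + space.attrs["mean"]


def delta_t(space: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between consecutive-level points per genotype.

    Rows: genotype x interval, with the interval's starting moisture
    level; every genotype must carry the full level grid.
    """
    levels = np.sort(space.index.get_level_values("level").unique())
    rows = []
    for g, sub in space.groupby(level="genotype", sort=True):
        sub = sub.droplevel("genotype").sort_index()
        if len(sub) != len(levels) or not np.array_equal(sub.index.to_numpy(), levels):
            raise ValueError(f"genotype {g!r} is missing grid levels")
        steps = np.sqrt((sub.to_numpy()[1:] - sub.to_numpy()[:-1]) ** 2 @ np.ones(sub.shape[1]))
        for i, d in enumerate(steps):
            rows.append(
                {
                    "genotype": g,
                    "interval": i + 1,
                    "level_start": levels[i],
                    "level_end": levels[i + 1],
                    "delta_t": float(d),
                }
            )
    return pd.DataFrame(rows)


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic, Welch-Satterthwaite df, p-value."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def species_contrast(series: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-interval Welch t-test of mean dT between the two species.

    `series` needs columns species, genotype, interval, level_start,
    delta_t.  Intervals where either species has fewer than two
    genotypes are flagged untestable (NaN statistics).
    """
    species = sorted(series["species"].unique())
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, got {species}")
    rows = []
    for (interval, level), sub in series.groupby(["interval", "level_start"], sort=True):
        a = sub.loc[sub["species"] == species[0], "delta_t"].to_numpy()
        b = sub.loc[sub["species"] == species[1], "delta_t"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            t = df = p = np.nan
        else:
            t, df, p = welch_test(a, b)
        rows.append(
            {
                "interval": interval,
                "level_start": level,
                "t": t,
                "df": df,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def trait_space_pca(space: pd.DataFrame):
    """Centered PCA of the scaled trait space.

    Returns (scores, loadings, variance_fractions).  Eigenvalues follow
    the sample-covariance convention (divisor n-1); each component's
    sign is fixed by making its largest-magnitude loading positive.
    """
    X = np.asarray(space, float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if not s[0] > 0:
        raise ValueError("rank-zero matrix")
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, : u.shape[1]]
    eigvals = s**2 / (n - 1)
    frac = eigvals / eigvals.sum()
    comp = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=space.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=space.columns, columns=comp)
    return scores, loadings, pd.Series(frac, index=comp, name="variance_fraction")
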
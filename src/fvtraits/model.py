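"""Fixed-effects reaction-norm model: terms, design matrices, least squares.

The full model for one trait in one species is

    trait ~ H + G + E + E2 + S + G:E + G:E2 + G:S

where H is the harvest cohort (categorical), G the genotype
(categorical), E the final gravimetric soil moisture in %, E2 its
square, and S a df=2 natural cubic spline of E.  E2 and S are treated as
main-effect terms in their own right (an interaction such as G:S only
requires G and S to be present), which is what lets selected models drop
E while keeping a nonlinear environmental predictor.

The full design is intentionally rank deficient: the natural-spline
space spanned by {intercept, S} contains every linear function of E, so
E is exactly aliased.  Fitting therefore uses a rank-revealing QR with
column pivoting; aliased columns are flagged and contribute zero to
predictions, and the AIC penalty counts the rank, not the column count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .splines import NaturalSplineBasis, SplineBasisDef

#: canonical term order; also the tie-break order during stepwise moves
TERM_ORDER: tuple[str, ...] = ("H", "G", "E", "E2", "S", "G:E", "G:E2", "G:S")

#: marginality: interaction -> main effects it requires
REQUIRES: dict[str, frozenset[str]] = {
    "G:E": frozenset({"G", "E"}),
    "G:E2": frozenset({"G", "E2"}),
    "G:S": frozenset({"G", "S"}),
}

FULL_MODEL: frozenset[str] = frozenset(TERM_ORDER)


def validate_terms(terms) -> frozenset[str]:
    """Check membership in the full-model scope and marginality closure."""
    terms = frozenset(terms)
    unknown = terms - FULL_MODEL
    if unknown:
        raise ValueError(f"unknown model terms: {sorted(unknown)}")
    for t in terms & REQUIRES.keys():
        missing = REQUIRES[t] - terms
        if missing:
            raise ValueError(
                f"term {t} violates marginality: requires {sorted(missing)}"
            )
    return terms


def sorted_terms(terms) -> list[str]:
    return [t for t in TERM_ORDER if t in terms]


def _contrasts(values: pd.Series, levels: list) -> tuple[np.ndarray, list[str]]:
    """Treatment coding against the lexicographically first level."""
    arr = np.asarray(values)
    cols = [(arr == lev).astype(float) for lev in levels[1:]]
    names = [str(lev) for lev in levels[1:]]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(arr), 0)), []


@dataclass
class DesignInfo:
    """Frozen encoding state so that prediction reuses the fit's coding."""

    genotype_levels: list
    cohort_levels: list
    basis: NaturalSplineBasis

    @classmethod
    def from_data(cls, data: pd.DataFrame, spline_df: int = 2) -> "DesignInfo":
        return cls(
            genotype_levels=sorted(data["genotype"].unique(), key=str),
            cohort_levels=sorted(data["cohort"].unique()),
            basis=NaturalSplineBasis.from_data(
                data["soil_moisture_final"].to_numpy(), df=spline_df
            ),
        )


def build_design_matrix(
    terms, data: pd.DataFrame, info: DesignInfo
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix for a term set.

    Returns the matrix (intercept always first) and per-column labels of
    the form ``term[detail]``.  Interactions are column-wise products of
    the genotype contrasts with the environmental column(s).
    """
    terms = validate_terms(terms)
    for t in terms:
        if t.startswith("G") and "genotype" not in data:
            raise ValueError("term requires a 'genotype' column")
        if t == "H" and "cohort" not in data:
            raise ValueError("term H requires a 'cohort' column")
    n = len(data)
    e = data["soil_moisture_final"].to_numpy(float)

    g_cols, g_names = _contrasts(data["genotype"], info.genotype_levels) if (
        "genotype" in data
    ) else (np.empty((n, 0)), [])

    env: dict[str, tuple[np.ndarray, list[str]]] = {
        "E": (e[:, None], ["E"]),
        "E2": ((e**2)[:, None], ["E2"]),
        "S": (info.basis(e), [f"S{k+1}" for k in range(info.basis.definition.df)]),
    }

    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["Intercept"]
    for t in sorted_terms(terms):
        if t == "H":
            cols, lab = _contrasts(data["cohort"], info.cohort_levels)
            blocks.append(cols)
            names += [f"H[{s}]" for s in lab]
        elif t == "G":
            blocks.append(g_cols)
            names += [f"G[{s}]" for s in g_names]
        elif t in env:
            cols, lab = env[t]
            blocks.append(cols)
            names += lab
        else:  # G:E, G:E2, G:S
            ecols, elab = env[t.split(":")[1]]
            prod = np.einsum("ij,ik->ijk", g_cols, ecols).reshape(n, -1)
            blocks.append(prod)
            names += [f"G[{g}]:{s}" for g in g_names for s in elab]
    return np.column_stack(blocks), names


@dataclass
class LeastSquaresFit:
    """Rank-revealing least-squares solution fragment."""

    coefficients: np.ndarray
    aliased: np.ndarray  # boolean mask of columns excluded as collinear
    rank: int
    rss: float
    n: int

    @property
    def df_resid(self) -> int:
        return self.n - self.rank


def fit_least_squares(design: np.ndarray, y: np.ndarray) -> LeastSquaresFit:
    """Minimize ||y - X b||^2 with exact collinearity handled by QR with
    column pivoting; aliased columns get coefficient zero."""
    X = np.asarray(design, float)
    y = np.asarray(y, float)
    n, p = X.shape
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if n <= rank:
        raise ValueError(f"unidentifiable fit: n={n} <= rank={rank}")
    keep = piv[:rank]
    coef = np.zeros(p)
    if rank:
        z = q[:, :rank].T @ y
        coef[keep] = linalg.solve_triangular(r[:rank, :rank], z)
    resid = y - X @ coef
    aliased = np.ones(p, bool)
    aliased[keep] = False
    return LeastSquaresFit(coef, aliased, rank, float(resid @ resid), n)


def model_aic(fit: LeastSquaresFit, rss_tol: float | None = None) -> float:
    """AIC for a least-squares fit: n*ln(RSS/n) + 2*rank.

    The Gaussian-likelihood constant is identical across candidate
    models and is dropped.  A perfect fit (RSS below tolerance) returns
    -inf; the stepwise search then prefers the smaller-rank perfect fit.
    """
    if rss_tol is None:
        rss_tol = 1e-12 * max(fit.n, 1)
    if fit.rss <= rss_tol:
        return -np.inf
    return fit.n * np.log(fit.rss / fit.n) + 2 * fit.rank
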
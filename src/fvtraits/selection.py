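"""Bidirectional stepwise AIC selection of reaction-norm models.

Each trait x species combination starts from the full 8-term model and
repeatedly applies the single-term deletion or addition (scope limited
to the full model's terms) that lowers the AIC the most, subject to
marginality (an interaction may only be present together with its main
effects, and a main effect cannot be deleted while an interaction needs
it).  The search stops when no move strictly improves the criterion.

A term whose design columns are entirely collinear with the rest of the
current model (zero effective df — e.g. the raw moisture term E next to
the natural spline) is deleted outright before AIC moves are weighed,
as the reference stepwise implementations do.  Remaining ties are
resolved deterministically: deletions are preferred over additions, and
within each kind candidates are tried in the fixed term order H, G, E,
E2, S, G:E, G:E2, G:S.  Perfect fits (RSS ~ 0) compare by rank, so the
search settles on the smallest perfect model it can reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    FULL_MODEL,
    REQUIRES,
    DesignInfo,
    LeastSquaresFit,
    build_design_matrix,
    fit_least_squares,
    model_aic,
    sorted_terms,
    validate_terms,
)

#: ties in AIC closer than this are treated as exact
AIC_TIE_TOL = 1e-10
MAX_STEPS = 50
MIN_ROWS_WARN = 20


@dataclass
class FittedTraitModel:
    """A selected (or directly fitted) reaction-norm model for one
    trait in one species, with everything needed to predict."""

    species: str
    trait: str
    terms: frozenset[str]
    info: DesignInfo
    column_names: list[str]
    fit: LeastSquaresFit
    aic: float
    trace: list[dict] = field(default_factory=list)

    @property
    def genotype_distinguishable(self) -> bool:
        """Does the model give genotypes distinct predicted curves?"""
        return bool(self.terms & {"G", "G:E", "G:E2", "G:S"})

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        if "genotype" in data:
            unknown = set(data["genotype"]) - set(self.info.genotype_levels)
            if unknown and self.genotype_distinguishable:
                raise ValueError(
                    f"genotypes absent from training data: {sorted(map(str, unknown))}"
                )
        X, _ = build_design_matrix(self.terms, data, self.info)
        return X @ self.fit.coefficients

    def record(self) -> dict:
        """JSON-serializable summary (terms, knots, coefficients, fit stats)."""
        d = self.info.basis.definition
        return {
            "species": self.species,
            "trait": self.trait,
            "terms": sorted_terms(self.terms),
            "boundary_knots": list(d.boundary_knots),
            "interior_knots": list(d.interior_knots),
            "coefficients": {
                name: (None if al else float(c))
                for name, c, al in zip(
                    self.column_names, self.fit.coefficients, self.fit.aliased
                )
            },
            "n": self.fit.n,
            "rank": self.fit.rank,
            "rss": self.fit.rss,
            "aic": None if math.isinf(self.aic) else self.aic,
        }


def _deletable(terms: frozenset[str]) -> list[str]:
    out = []
    for t in sorted_terms(terms):
        needed_by = [i for i, req in REQUIRES.items() if i in terms and t in req]
        if not needed_by:
            out.append(t)
    return out


def _addable(terms: frozenset[str], scope: frozenset[str]) -> list[str]:
    out = []
    for t in sorted_terms(scope - terms):
        if REQUIRES.get(t, frozenset()) <= terms:
            out.append(t)
    return out


def _fit_terms(terms, data, info, y, rss_tol):
    X, names = build_design_matrix(terms, data, info)
    fit = fit_least_squares(X, y)
    return fit, names, model_aic(fit, rss_tol)


def _better(cand: tuple[float, int], cur: tuple[float, int]) -> bool:
    """Strict improvement of (aic, rank); perfect fits compare by rank."""
    ca, cr = cand
    ba, br = cur
    if math.isinf(ca) and math.isinf(ba):
        return cr < br
    return ca < ba - AIC_TIE_TOL


def _tie(a: float, b: float) -> bool:
    if math.isinf(a) and math.isinf(b):
        return True
    return abs(a - b) <= AIC_TIE_TOL


def stepwise_select(
    data: pd.DataFrame,
    trait: str,
    species: str = "",
    full: frozenset[str] = FULL_MODEL,
    spline_df: int = 2,
) -> FittedTraitModel:
    """Select a reaction-norm model for one trait by bidirectional
    stepwise AIC starting from (and scoped to) the full model.

    `data` must hold one species' rows with columns genotype, cohort,
    soil_moisture_final and the trait; rows with a missing trait value
    are dropped here.
    """
    full = validate_terms(full)
    rows = data.dropna(subset=[trait])
    if len(rows) < MIN_ROWS_WARN:
        import warnings

        warnings.warn(
            f"only {len(rows)} non-missing rows for {species or 'data'}/{trait};"
            " selection attempted anyway",
            stacklevel=2,
        )
    info = DesignInfo.from_data(rows, spline_df=spline_df)
    y = rows[trait].to_numpy(float)
    rss_tol = 1e-14 * (float(y @ y) + 1.0)

    terms = full
    fit, names, aic = _fit_terms(terms, rows, info, y, rss_tol)
    trace: list[dict] = []
    for _ in range(MAX_STEPS):
        candidates: list[tuple[str, str]] = [("-", t) for t in _deletable(terms)]
        candidates += [("+", t) for t in _addable(terms, full)]
        best = None
        aliased_deletions = []  # terms contributing zero rank (and zero RSS)
        tie_deletion = None  # rank-reducing deletion whose AIC ties exactly
        step_log = {"terms": sorted_terms(terms), "aic": aic, "candidates": {}}
        for move, t in candidates:
            cterms = terms - {t} if move == "-" else terms | {t}
            cfit, cnames, caic = _fit_terms(cterms, rows, info, y, rss_tol)
            step_log["candidates"][move + t] = caic
            key = (caic, cfit.rank)
            if move == "-" and _tie(caic, aic):
                if cfit.rank == fit.rank:
                    aliased_deletions.append((t, key, cterms, cfit, cnames))
                elif tie_deletion is None:
                    tie_deletion = (key, cterms, cfit, cnames)
            if best is None or _better(key, best[0]):
                best = (key, cterms, cfit, cnames)
        trace.append(step_log)
        if aliased_deletions:
            # a term whose columns are wholly collinear with the rest of
            # the model (e.g. E alongside the spline) contributes nothing:
            # remove it before weighing AIC moves, last-in-term-order
            # first, exactly as the reference stepwise implementation
            # eliminates zero-df terms
            _, key, terms, fit, names = aliased_deletions[-1]
            aic = key[0]
        elif best is not None and _better(best[0], (aic, fit.rank)):
            (aic, _), terms, fit, names = best
        elif tie_deletion is not None:
            # an exact AIC tie against the incumbent: prefer the smaller
            # model rather than letting floating-point jitter decide
            (aic, _), terms, fit, names = tie_deletion
        else:
            break
    return FittedTraitModel(species, trait, terms, info, names, fit, aic, trace)


def select_all(
    table: pd.DataFrame,
    traits: list[str],
    spline_df: int = 2,
    full: frozenset[str] = FULL_MODEL,
) -> list[FittedTraitModel]:
    """Run selection separately per species for every trait."""
    models = []
    for species, sub in table.groupby("species", sort=True):
        for trait in traits:
            if trait not in sub or sub[trait].notna().sum() == 0:
                continue
            models.append(
                stepwise_select(
                    sub, trait, species=str(species), full=full, spline_df=spline_df
                )
            )
    return models


def term_matrix(models: list[FittedTraitModel]) -> pd.DataFrame:
    """Selected-term summary, one row per trait x species, 'x' where a
    term entered the final model and an em dash where it did not."""
    rows = []
    for m in models:
        row = {"trait": m.trait, "species": m.species}
        row.update({t: ("x" if t in m.terms else "—") for t in sorted_terms(FULL_MODEL)})
        rows.append(row)
    return pd.DataFrame(rows)
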
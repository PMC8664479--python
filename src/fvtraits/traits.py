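"""Composite-trait derivation from raw destructive-harvest measurements.

Derived quantities follow the standard definitions:

    RWC        = (mass_fresh - mass_dry_leaf) / (mass_turgid - mass_dry_leaf)
    SLA        = leaf_area / mass_dry_leaf            [mm^2 / g]
    root:shoot = root_mass / shoot_mass
    biomass    = root_mass + shoot_mass
    C:N        = C_content / N_content

Undefined ratios (turgid == dry, zero shoot mass, zero N) are flagged
missing (NaN) rather than raised, mirroring how a real harvest sheet is
cleaned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RAW_COLUMNS = [
    "mass_fresh",
    "mass_turgid",
    "mass_dry_leaf",
    "leaf_area",
    "shoot_mass",
    "root_mass",
    "C_content",
    "N_content",
    "d13C",
    "d15N",
    "green_area",
]


def validate_raw(raw: pd.DataFrame) -> None:
    """Enforce the physical ordering turgid >= fresh >= dry > 0 and
    non-negative masses/areas where the columns are present."""
    def col(name):
        return raw[name].to_numpy(float) if name in raw else None

    fresh, turgid, dry = col("mass_fresh"), col("mass_turgid"), col("mass_dry_leaf")
    if fresh is not None and turgid is not None and dry is not None:
        ok = np.isnan(fresh) | np.isnan(turgid) | np.isnan(dry) | (
            (turgid >= fresh) & (fresh >= dry) & (dry > 0)
        )
        if not ok.all():
            bad = np.flatnonzero(~ok).tolist()
            raise ValueError(f"mass ordering turgid>=fresh>=dry>0 violated at rows {bad}")
    for name in ("leaf_area", "shoot_mass", "root_mass"):
        v = col(name)
        if v is not None and np.nanmin(v, initial=0.0) < 0:
            raise ValueError(f"negative values in {name}")


def derive_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Append derived trait columns (RWC, SLA, root_shoot, biomass, C_N)."""
    validate_raw(raw)
    out = raw.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        if {"mass_fresh", "mass_turgid", "mass_dry_leaf"} <= set(raw):
            denom = out["mass_turgid"] - out["mass_dry_leaf"]
            rwc = (out["mass_fresh"] - out["mass_dry_leaf"]) / denom
            out["RWC"] = rwc.where(denom > 0)
        if {"leaf_area", "mass_dry_leaf"} <= set(raw):
            out["SLA"] = (out["leaf_area"] / out["mass_dry_leaf"]).where(
                out["mass_dry_leaf"] > 0
            )
        if {"root_mass", "shoot_mass"} <= set(raw):
            out["root_shoot"] = (out["root_mass"] / out["shoot_mass"]).where(
                out["shoot_mass"] > 0
            )
            out["biomass"] = out["root_mass"] + out["shoot_mass"]
        if {"C_content", "N_content"} <= set(raw):
            out["C_N"] = (out["C_content"] / out["N_content"]).where(
                out["N_content"] > 0
            )
    return out
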
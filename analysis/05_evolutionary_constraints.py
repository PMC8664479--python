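"""G-matrix constraint statistics along the soil-moisture gradient.

At each grid level the genetic covariance matrix G is approximated from
mean-standardized genotype means (traits restricted per species to
those with genotype terms in the selected models); its eigenvalues give
the effective number of dimensions nD, the maximum evolvability emax,
the total genetic variance vT, and the first-eigenvector share.
"""

import argparse
from pathlib import Path

import pandas as pd

from fvtraits.constraints import constraint_curves
from fvtraits.predict import moisture_grid

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    gm = pd.read_csv(RESULTS / "genotype_means.csv")
    terms = pd.read_csv(RESULTS / "model_terms.csv")
    geno_cols = ["G", "G:E", "G:E2", "G:S"]
    traits_by_species = {
        sp: sub.loc[(sub[geno_cols] == "x").any(axis=1), "trait"].tolist()
        for sp, sub in terms.groupby("species")
    }
    curves = constraint_curves(gm, moisture_grid(), traits_by_species)
    curves.to_csv(RESULTS / "constraints.csv", index=False)

    for sp, sub in curves.groupby("species"):
        sub = sub.dropna(subset=["vT"]).sort_values("level")
        dry, wet = sub.iloc[0], sub.iloc[-1]
        trend = "dry" if dry["vT"] > wet["vT"] else "wet"
        print(
            f"{sp}: nD {sub['nD'].min():.2f}-{sub['nD'].max():.2f}, "
            f"emax {sub['emax'].min():.3f}-{sub['emax'].max():.3f}, "
            f"vT {sub['vT'].min():.4f}-{sub['vT'].max():.4f} "
            f"(total genetic variance highest at the {trend} end); "
            f"first-eigenvector share {100*sub['prop1'].min():.0f}-{100*sub['prop1'].max():.0f}%"
        )


if __name__ == "__main__":
    main()
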
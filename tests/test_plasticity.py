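"""Scaled trait space, dT plasticity, species contrasts and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fvtraits.plasticity import (
    delta_t,
    scaled_trait_space,
    species_contrast,
    trait_space_pca,
    unscale,
    welch_test,
)
from fvtraits.predict import moisture_grid


def mean_grid_from(values: dict, species="sp") -> pd.DataFrame:
    levels = moisture_grid()
    rows = [
        {"species": species, "trait": t, "genotype": g, "level": lev, "value": val}
        for (t, g), v in values.items()
        for lev, val in zip(levels, v)
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def random_space(rng):
    values = {
        (t, g): rng.normal(size=20) for t in "ABCD" for g in ("g1", "g2", "g3")
    }
    return scaled_trait_space(mean_grid_from(values), "sp")


class TestScaling:
    def test_three_point_column_and_invertibility(self, rng):
        values = {("A", "g1"): np.arange(20.0), ("B", "g1"): rng.normal(size=20)}
        space = scaled_trait_space(mean_grid_from(values), "sp")
        col = np.sort(space["A"].to_numpy())[:3]
        # symmetric case {1,2,3} -> {-1,0,1} with the n-1 divisor applies
        # to any 3 evenly spaced values after restriction
        s = pd.Series([1.0, 2.0, 3.0])
        z = (s - s.mean()) / s.std(ddof=1)
        assert np.allclose(z, [-1, 0, 1])
        assert np.allclose(space.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(space.std(axis=0, ddof=1), 1.0, atol=1e-10)
        back = unscale(space)
        assert np.allclose(
            back.sort_index().to_numpy(),
            pd.DataFrame(
                {"A": np.arange(20.0), "B": values[("B", "g1")]},
                index=back.sort_index().index,
            ).to_numpy(),
            atol=1e-12,
        )

    def test_constant_trait_rejected(self):
        values = {("A", "g1"): np.full(20, 5.0), ("B", "g1"): np.arange(20.0)}
        with pytest.raises(ValueError, match="A"):
            scaled_trait_space(mean_grid_from(values), "sp")

    def test_pooled_scaling_differs_from_subset_scaling(self):
        # scaling over pooled rows then subsetting is not the same as
        # scaling the subset: the pooled mean mixes both genotypes
        values = {("A", "g1"): np.arange(20.0), ("A", "g2"): np.arange(20.0) + 10.0,
                  ("B", "g1"): np.ones(20) * np.arange(20), ("B", "g2"): -np.arange(20.0)}
        space = scaled_trait_space(mean_grid_from(values), "sp")
        sub = space.xs("g1", level="genotype")["A"]
        assert abs(sub.mean()) > 0.1  # pooled scaling leaves subset off-center
        resc = (sub - sub.mean()) / sub.std(ddof=1)
        assert not np.allclose(sub, resc)


class TestDeltaT:
    def test_identical_consecutive_points_give_zero(self):
        values = {("A", "g1"): np.arange(20.0), ("B", "g1"): np.arange(20.0)}
        space = scaled_trait_space(mean_grid_from(values), "sp")
        space["B"] = 1.0  # freeze one coordinate post-scaling
        space["A"] = 2.0
        d = delta_t(space)
        assert np.allclose(d["delta_t"], 0.0)

    def test_three_four_five(self):
        values = {("A", "g1"): np.arange(20.0), ("B", "g1"): np.arange(20.0)}
        space = scaled_trait_space(mean_grid_from(values), "sp")
        a = np.zeros(20)
        b = np.zeros(20)
        a[1:] = 3.0  # one step of 3 in A and 4 in B, then constant
        b[1:] = 4.0
        space["A"], space["B"] = a, b
        d = delta_t(space).sort_values("interval")
        assert d["delta_t"].iloc[0] == pytest.approx(5.0)
        assert np.allclose(d["delta_t"].iloc[1:], 0.0)

    def test_matches_loop_oracle(self, random_space):
        d = delta_t(random_space).set_index(["genotype", "interval"])
        levels = np.sort(random_space.index.get_level_values("level").unique())
        for g in ("g1", "g2", "g3"):
            sub = random_space.xs(g, level="genotype").sort_index()
            for i in range(19):
                acc = 0.0
                for trait in sub.columns:
                    acc += (sub[trait].iloc[i] - sub[trait].iloc[i + 1]) ** 2
                assert d.loc[(g, i + 1), "delta_t"] == pytest.approx(
                    np.sqrt(acc), abs=1e-12
                )

    def test_rotation_invariance_and_homogeneity(self, random_space, rng):
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = random_space.copy()
        rotated.iloc[:, :] = random_space.to_numpy() @ q
        assert np.allclose(
            delta_t(random_space)["delta_t"], delta_t(rotated)["delta_t"], atol=1e-10
        )
        doubled = random_space * 2.0
        assert np.allclose(
            2.0 * delta_t(random_space)["delta_t"],
            delta_t(doubled)["delta_t"],
            atol=1e-10,
        )

    def test_missing_level_rejected(self, random_space):
        with pytest.raises(ValueError, match="missing"):
            delta_t(random_space.iloc[1:])


class TestSpeciesContrast:
    def test_welch_closed_form_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, df, p = welch_test(a, b)
        se = np.sqrt(1.0 / 3 + 1.0 / 3)  # both sample variances are 1
        t_hand = (a.mean() - b.mean()) / se
        df_hand = se**4 / ((1.0 / 3) ** 2 / 2 + (1.0 / 3) ** 2 / 2)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_label_swap_negates_t_keeps_p(self):
        a, b = np.array([1.0, 2.0, 5.0]), np.array([2.0, 4.0, 6.0])
        t1, _, p1 = welch_test(a, b)
        t2, _, p2 = welch_test(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_identical_groups_give_t0_p1(self):
        t, _, p = welch_test(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_per_interval_frame(self, rng):
        rows = []
        for sp, shift in (("sp1", 0.0), ("sp2", 2.0)):
            for g in range(3):
                for i in range(1, 20):
                    rows.append(
                        {
                            "species": sp,
                            "genotype": f"{sp}g{g}",
                            "interval": i,
                            "level_start": 30.0 + (i - 1) * 70 / 19,
                            "delta_t": rng.normal(1.0 + shift, 0.05),
                        }
                    )
        res = species_contrast(pd.DataFrame(rows))
        assert len(res) == 19
        assert res["significant"].all()
        assert (res["t"] < 0).all()  # sp1 (first label) has the smaller mean dT


class TestPCA:
    def test_perfect_line_gives_single_component(self):
        x = np.linspace(-2, 2, 30)
        space = pd.DataFrame(
            {"A": x, "B": x},
            index=pd.MultiIndex.from_product(
                [["g"], range(30)], names=["genotype", "level"]
            ),
        )
        scores, loadings, frac = trait_space_pca(space)
        assert frac.iloc[0] == pytest.approx(1.0)
        assert np.allclose(loadings["PC1"], [np.sqrt(0.5), np.sqrt(0.5)])

    def test_variance_fractions_and_reconstruction(self, random_space):
        scores, loadings, frac = trait_space_pca(random_space)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        X = random_space.to_numpy()
        Xc = X - X.mean(axis=0)
        assert np.allclose(scores.to_numpy() @ loadings.to_numpy().T, Xc, atol=1e-10)
        # sign convention: the largest-magnitude loading of each PC is positive
        L = loadings.to_numpy()
        assert np.all(L[np.abs(L).argmax(axis=0), np.arange(L.shape[1])] > 0)

    def test_eigenvalue_sum_equals_covariance_trace(self, random_space):
        X = random_space.to_numpy()
        n = X.shape[0]
        Xc = X - X.mean(axis=0)
        scores, _, frac = trait_space_pca(random_space)
        eig = (scores.to_numpy() ** 2).sum(axis=0) / (n - 1)
        assert eig.sum() == pytest.approx(np.trace(np.cov(Xc, rowvar=False)), abs=1e-10)
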
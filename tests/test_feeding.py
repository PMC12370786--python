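"""Diet CWMs, niche summaries, permutation F tests and trait matching."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hoppertraits import (
    FeedingConfig,
    cwm,
    cwm_table,
    diet_difference_test,
    gen_feeding,
    niche_summary,
    trait_matching,
)


class TestCWM:
    def test_point_mass(self):
        c = pd.Series({"p1": 0.0, "p2": 1.5, "p3": 0.0})
        t = pd.Series({"p1": 10.0, "p2": 22.0, "p3": 31.0})
        assert cwm(c, t) == pytest.approx(22.0)

    def test_equal_split(self):
        c = pd.Series({"p1": 2.0, "p2": 2.0})
        t = pd.Series({"p1": 10.0, "p2": 20.0})
        assert cwm(c, t) == pytest.approx(15.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.Series(rng.uniform(0, 3, 8), index=[f"p{i}" for i in range(8)])
        t = pd.Series(rng.uniform(5, 50, 8), index=c.index)
        assert cwm(2.0 * c, t) == pytest.approx(cwm(c, t), rel=1e-12)

    def test_zero_total_undefined(self):
        c = pd.Series({"p1": 0.0, "p2": 0.0})
        t = pd.Series({"p1": 10.0, "p2": 20.0})
        with pytest.warns(UserWarning, match="zero total"):
            assert np.isnan(cwm(c, t))

    def test_convexity_bounds(self, traits14, plants16):
        fd = gen_feeding(traits14, plants16, FeedingConfig(seed=4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cw = cwm_table(fd, plants16)
        mat = fd.loc[cw.index, plants16.index].to_numpy()
        for col, trait in [("cwm_ldmc", "ldmc"), ("cwm_sla", "sla"), ("cwm_cn", "cn_ratio")]:
            vals = plants16[trait].to_numpy()
            for k, row in enumerate(mat):
                eaten = vals[row > 0]
                assert eaten.min() - 1e-9 <= cw[col].iloc[k] <= eaten.max() + 1e-9

    def test_zero_total_individuals_excluded(self, plants16):
        fd = pd.DataFrame(
            {
                "species_id": ["a", "a"],
                "subfamily": ["A", "A"],
                **{p: [1.0, 0.0] for p in plants16.index},
            },
            index=pd.Index(["i1", "i2"], name="individual_id"),
        )
        with pytest.warns(UserWarning, match="zero total"):
            cw = cwm_table(fd, plants16)
        assert list(cw.index) == ["i1"]


def _cwm_frame(groups, values, subfamilies=None):
    n = len(values)
    return pd.DataFrame(
        {
            "species_id": groups,
            "subfamily": subfamilies if subfamilies is not None else ["X"] * n,
            "cwm_ldmc": values,
            "cwm_sla": values,
            "cwm_cn": values,
            "total_consumed": 1.0,
        },
        index=pd.Index([f"i{k}" for k in range(n)], name="individual_id"),
    )


class TestNicheSummary:
    def test_identical_individuals_zero_sd(self):
        cw = _cwm_frame(["a"] * 3, [5.0, 5.0, 5.0])
        out = niche_summary(cw, "species")
        assert out.loc["a", "cwm_ldmc_sd"] == pytest.approx(0.0)

    def test_two_individuals_hand_values(self):
        cw = _cwm_frame(["a", "a"], [1.0, 3.0])
        out = niche_summary(cw, "species")
        assert out.loc["a", "cwm_ldmc_mean"] == pytest.approx(2.0)
        assert out.loc["a", "cwm_ldmc_sd"] == pytest.approx(np.sqrt(2.0))

    def test_singleton_group_sd_undefined(self):
        cw = _cwm_frame(["a", "b", "b"], [1.0, 2.0, 4.0])
        out = niche_summary(cw, "species")
        assert np.isnan(out.loc["a", "cwm_ldmc_sd"])
        assert out.loc["b", "n"] == 2

    def test_subfamily_separation_with_guild_structured_kernel(self, plants16):
        """When subfamilies block along the incisor-strength axis, a strong
        matching kernel separates subfamily diet means beyond within-group SD."""
        from hoppertraits import make_species_pool

        pool = make_species_pool(14, seed=6, subfamily_assignment="by_trait")
        g = pool.trait_table()
        fd = gen_feeding(
            g, plants16,
            FeedingConfig(beta_matching=2.0, beta_cn=0, beta_bv=0,
                          noise_sd=0.3, n_replicates_per_species=8, seed=1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cw = cwm_table(fd, plants16)
        out = niche_summary(cw, "subfamily")
        spread = out["cwm_ldmc_mean"].max() - out["cwm_ldmc_mean"].min()
        assert spread > out["cwm_ldmc_sd"].mean()

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            niche_summary(_cwm_frame(["a", "a"], [1, 2]), "genus")


class TestDietDifferenceTest:
    def test_degenerate_constant_data(self):
        cw = _cwm_frame(["a", "a", "b", "b"], [2.0, 2.0, 2.0, 2.0])
        res = diet_difference_test(cw, "species", "ldmc", n_perm=199, seed=0)
        assert res["p_value"] == 1.0

    def test_disjoint_groups_hit_permutation_floor(self):
        rng = np.random.default_rng(0)
        cw = _cwm_frame(
            ["a"] * 10 + ["b"] * 10,
            np.concatenate([rng.uniform(0, 1, 10), rng.uniform(10, 11, 10)]),
        )
        res = diet_difference_test(cw, "species", "ldmc", n_perm=999, seed=1)
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_f_matches_scipy(self):
        rng = np.random.default_rng(3)
        cw = _cwm_frame(["a"] * 5 + ["b"] * 6 + ["c"] * 4, rng.normal(0, 1, 15))
        res = diet_difference_test(cw, "species", "ldmc", n_perm=99, seed=0)
        f_ref = stats.f_oneway(
            *[cw.loc[cw.species_id == g, "cwm_ldmc"] for g in ("a", "b", "c")]
        ).statistic
        assert res["F"] == pytest.approx(f_ref, rel=1e-10)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """Two groups of three: all C(6,3)=20 relabelings enumerable."""
        values = np.array([0.1, 0.9, 1.3, 2.0, 2.2, 3.1])
        cw = _cwm_frame(["a"] * 3 + ["b"] * 3, values)
        res = diet_difference_test(cw, "species", "ldmc", n_perm=9999, seed=7)

        def f_stat(labels):
            g1 = values[np.array(labels)]
            g2 = values[~np.array(labels)]
            return stats.f_oneway(g1, g2).statistic

        obs = f_stat([True, True, True, False, False, False])
        stats_all = [
            f_stat([i in combo for i in range(6)])
            for combo in itertools.combinations(range(6), 3)
        ]
        p_exact = np.mean([s >= obs - 1e-12 for s in stats_all])
        assert res["p_value"] == pytest.approx(p_exact, abs=0.02)

    def test_few_permutations_warn(self):
        cw = _cwm_frame(["a", "a", "b", "b"], [1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="n_perm"):
            diet_difference_test(cw, "species", "ldmc", n_perm=19, seed=0)

    def test_requires_two_groups_of_two(self):
        cw = _cwm_frame(["a", "a", "b"], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            diet_difference_test(cw, "species", "ldmc")


class TestTraitMatching:
    def _setup(self, slope, noise_sd, seed=0, n_rep=12):
        rng = np.random.default_rng(seed)
        from hoppertraits import make_species_pool

        pool = make_species_pool(14, seed=seed)
        g = pool.trait_table()
        x = np.log(g["incisor_strength"])
        rows = []
        for sp in g.index:
            for k in range(n_rep):
                rows.append(
                    {
                        "species_id": sp,
                        "subfamily": g.loc[sp, "subfamily"],
                        "cwm_ldmc": 300 + slope * x[sp] + rng.normal(0, noise_sd),
                        "cwm_sla": 15.0,
                        "cwm_cn": 30.0,
                        "total_consumed": 1.0,
                    }
                )
        return g, pd.DataFrame(rows).set_index(
            pd.Index([f"i{k}" for k in range(len(rows))], name="individual_id")
        )

    def test_exact_linear_recovery(self):
        g, cw = self._setup(slope=12.0, noise_sd=0.0)
        res = trait_matching(g, cw, ("incisor_strength", "ldmc"))
        assert res.slope == pytest.approx(12.0, rel=1e-9)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_null_slope_within_two_se(self):
        g, cw = self._setup(slope=0.0, noise_sd=5.0, seed=4)
        res = trait_matching(g, cw, ("incisor_strength", "ldmc"))
        assert abs(res.slope) < 2 * res.slope_se

    def test_invalid_pair_rejected(self, traits14):
        cw = _cwm_frame(["a", "a", "b", "b"], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="pair"):
            trait_matching(traits14, cw, ("body_volume", "ldmc"))

    def test_small_subfamily_merged_with_warning(self):
        g, cw = self._setup(slope=5.0, noise_sd=1.0, seed=2)
        g = g.copy()
        g.loc[g.index[0], "subfamily"] = "Singleton"
        cw.loc[cw["species_id"] == g.index[0], "subfamily"] = "Singleton"
        with pytest.warns(UserWarning, match="merged"):
            res = trait_matching(g, cw, ("incisor_strength", "ldmc"))
        assert np.isfinite(res.slope)

    def test_matches_statsmodels_formula_fit(self):
        """Dummy-coded fit agrees with an independent formula-interface fit."""
        import statsmodels.formula.api as smf

        g, cw = self._setup(slope=8.0, noise_sd=3.0, seed=9)
        res = trait_matching(g, cw, ("incisor_strength", "ldmc"))
        df = cw.copy()
        df["x"] = np.log(g["incisor_strength"]).reindex(df["species_id"]).to_numpy()
        ref = smf.ols("cwm_ldmc ~ x + C(subfamily)", data=df).fit()
        assert res.slope == pytest.approx(ref.params["x"], rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalues["x"], rel=1e-8)
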
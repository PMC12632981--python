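import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from hippodti.errors import ConfigurationError, DataError
from hippodti.groupstats import (
    build_design,
    fdr_bh,
    fit_lm,
    games_howell,
    hemisphere_group_screen,
    nested_f_test,
    subfield_group_analysis,
    vertexwise_contrast,
    welch_anova,
)


def random_cohort(rng, n=60):
    return pd.DataFrame(
        {
            "age": rng.uniform(55, 90, n),
            "hemi": rng.choice(["L", "R"], n),
            "group": rng.choice(["AD", "MCI", "CN"], n),
            "sex": rng.choice(["F", "M"], n),
            "value": rng.normal(0, 1, n),
        }
    )


class TestLinearModel:
    def test_exact_line_zero_rss(self):
        data = pd.DataFrame({"age": np.arange(10.0)})
        fit = fit_lm(data, 2.0 * data["age"].to_numpy() + 1.0, ["age"])
        np.testing.assert_allclose(fit.coef, [1.0, 2.0], atol=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_intercept_only_rss(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        fit = fit_lm(pd.DataFrame(index=range(30)), y, [])
        assert fit.rss == pytest.approx(np.sum((y - y.mean()) ** 2), abs=1e-10)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"age": rng.uniform(50, 90, 50), "sex": rng.choice(["F", "M"], 50)}
        )
        y = rng.normal(size=50)
        fit = fit_lm(data, y, ["age", "sex"])
        X, _ = build_design(data, ["age", "sex"])
        beta, rss, df = oracles.ols_normal_equations(X, y)
        np.testing.assert_allclose(fit.coef, beta, atol=1e-8)
        assert fit.rss == pytest.approx(rss, abs=1e-8)
        assert fit.df_resid == df

    def test_rank_deficiency_names_terms(self):
        data = pd.DataFrame({"age": np.ones(20), "sex": ["F"] * 20})
        with pytest.raises(ConfigurationError, match="collinear"):
            fit_lm(data, np.arange(20.0), ["age", "sex"])


class TestNestedF:
    def test_matches_two_fit_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            data = random_cohort(rng)
            reduced = ["age", "hemi", "group", "age:group", "age:hemi"]
            full = reduced + ["hemi:group"]
            res = nested_f_test(data, "value", reduced, full)
            Xr, _ = build_design(data, reduced)
            Xf, _ = build_design(data, full)
            _, rss_r, df_r = oracles.ols_normal_equations(Xr, data["value"])
            _, rss_f, df_f = oracles.ols_normal_equations(Xf, data["value"])
            F, p = oracles.f_test_from_rss(rss_r, df_r, rss_f, df_f)
            assert res.F == pytest.approx(F, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(3)
        data = random_cohort(rng)
        with pytest.raises(ConfigurationError):
            nested_f_test(data, "value", ["age", "sex"], ["age", "hemi"])

    def test_perfect_fit_degenerate_flag(self):
        data = pd.DataFrame({"age": np.arange(10.0), "z": np.arange(10.0) ** 2})
        y = 1.0 + 2.0 * data["z"].to_numpy()
        res = nested_f_test(data, y, ["age"], ["age", "z"])
        assert res.degenerate
        assert res.p <= np.finfo(float).tiny

    def test_null_p_uniform(self):
        """Type-I calibration: an irrelevant added term gives uniform p."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(400):
            n = 50
            data = pd.DataFrame(
                {"age": rng.uniform(0, 1, n), "z": rng.normal(size=n)}
            )
            y = rng.normal(size=n)
            pvals.append(nested_f_test(data, y, ["age"], ["age", "z"]).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestWelch:
    def test_matches_formula_transcription(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [
                rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), rng.integers(5, 40))
                for _ in range(k)
            ]
            res = welch_anova(groups)
            F, df1, df2, p = oracles.welch_anova_oracle(groups)
            assert res.F == pytest.approx(F, abs=1e-6)
            assert res.df_den == pytest.approx(df2, abs=1e-6)
            assert res.p == pytest.approx(p, abs=1e-6)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 20), rng.normal(0.5, 2, 30), rng.normal(1, 3, 25)]
        res = welch_anova(groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [20, 30, 25]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.F == pytest.approx(float(ref["F"][0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), abs=1e-10)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 2, 25)
        res = welch_anova([a, b])
        t, df, p = oracles.welch_t_test(a, b)
        assert res.F == pytest.approx(t**2, abs=1e-10)
        assert res.df_den == pytest.approx(df, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_fixed_three_group_example(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([10.0, 11, 12])]
        res = welch_anova(groups)
        F, _, df2, p = oracles.welch_anova_oracle(groups)
        assert res.F == pytest.approx(F, abs=1e-10)

    def test_type_one_error_under_unequal_variances(self):
        """Rejection rate stays near alpha with sigma ratio 1:3 and unequal n."""
        rng = np.random.default_rng(8)
        n = (12, 20, 35)
        sd = (1.0, 2.0, 3.0)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0.0, s, m) for m, s in zip(n, sd)]
            rejections += welch_anova(groups).p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_preconditions(self):
        with pytest.raises(DataError):
            welch_anova([np.array([1.0, 2.0])])
        with pytest.raises(DataError):
            welch_anova([np.array([1.0, 1.0]), np.array([2.0, 3.0])])


class TestGamesHowell:
    def test_identical_groups_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = games_howell([a, a.copy()])
        assert out["mean_diff"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_k2_reduces_to_welch_t(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 18), rng.normal(0.8, 2.5, 28)
        out = games_howell([a, b])
        t, df, p = oracles.welch_t_test(a, b)
        assert out["t"].iloc[0] == pytest.approx(abs(t), abs=1e-10)
        assert out["df"].iloc[0] == pytest.approx(df, abs=1e-8)
        assert out["p"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_matches_oracle_and_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        for _ in range(20):
            groups = [
                rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), rng.integers(8, 30))
                for _ in range(3)
            ]
            out = games_howell(groups, ["a", "b", "c"])
            ora = oracles.games_howell_oracle(groups)
            for row, (t, df, p) in zip(out.itertuples(), ora):
                assert row.t == pytest.approx(t, abs=1e-8)
                assert row.p == pytest.approx(p, abs=1e-6)
        df_pg = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pg.pairwise_gameshowell(data=df_pg, dv="y", between="g")
        np.testing.assert_allclose(out["p"].to_numpy(), ref["pval"].to_numpy(), atol=1e-6)


class TestFDR:
    def test_single_p_unchanged(self):
        rej, adj = fdr_bh([0.03])
        assert adj[0] == 0.03 and rej[0]

    def test_stepup_example(self):
        p = [0.001, 0.01, 0.02, 0.8, 0.9]
        rej, adj = fdr_bh(p, alpha=0.05)
        assert list(rej) == [True, True, True, False, False]
        np.testing.assert_array_equal(rej, oracles.bh_stepup_bruteforce(p, 0.05))

    def test_all_ones(self):
        rej, adj = fdr_bh(np.ones(10))
        assert not rej.any()
        np.testing.assert_allclose(adj, 1.0)

    def test_matches_bruteforce_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(2, 20))
            rej, adj = fdr_bh(p, alpha=0.05)
            np.testing.assert_array_equal(rej, oracles.bh_stepup_bruteforce(p, 0.05))
            rej2, adj2, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, adj2, atol=1e-12)

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=30)
        _, adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestAssembledAnalyses:
    def make_parcel_table(self, rng, effect=None, n=(20, 20, 20)):
        parcels = ["Sub", "CA1", "CA2", "CA3", "DG/CA4"]
        rows = []
        for gi, (g, ng) in enumerate(zip(("AD", "MCI", "CN"), n)):
            for i in range(ng):
                base = rng.normal(0, 1)
                for parcel in parcels:
                    shift = effect[g] if effect else 0.0
                    rows.append(
                        {
                            "participant": f"{g}{i}",
                            "group": g,
                            "parcel": parcel,
                            "metric": "MD",
                            "value": shift + base * 0.1 + rng.normal(0, 0.5),
                        }
                    )
        return pd.DataFrame(rows)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(13)
        n_sig = 0
        reps = 60
        for _ in range(reps):
            tab = self.make_parcel_table(rng)
            rep = subfield_group_analysis(tab, "MD")
            n_sig += int(rep.loc[rep["kind"] == "anova", "significant"].sum())
        # expected false positives ~= 5 * 0.05 per replicate under FDR
        assert n_sig / (5 * reps) < 0.10

    def test_effect_ordering_recovered(self):
        rng = np.random.default_rng(14)
        tab = self.make_parcel_table(
            rng, effect={"AD": 2.0, "MCI": 1.0, "CN": 0.0}, n=(40, 30, 50)
        )
        rep = subfield_group_analysis(tab, "MD")
        anova = rep[rep["kind"] == "anova"]
        assert anova["significant"].all()
        post = rep[rep["kind"] == "posthoc"]
        assert len(post) == 15
        assert (post["p"] < 0.01).all()

    def test_missing_parcel_excluded_with_n(self):
        rng = np.random.default_rng(15)
        tab = self.make_parcel_table(rng)
        tab = tab[~((tab["participant"] == "AD0") & (tab["parcel"] == "CA2"))]
        rep = subfield_group_analysis(tab, "MD")
        anova = rep[rep["kind"] == "anova"].set_index("parcel")
        assert anova.loc["CA2", "n"] == anova.loc["CA1", "n"] - 1

    def test_hemisphere_screen_null_averages_everything(self):
        rng = np.random.default_rng(16)
        rows = []
        for g in ("AD", "MCI", "CN"):
            for i in range(30):
                age = rng.uniform(55, 90)
                for hemi in ("L", "R"):
                    for metric in ("MD", "thickness"):
                        rows.append(
                            {
                                "participant": f"{g}{i}", "group": g, "age": age,
                                "sex": "F", "hemi": hemi, "metric": metric,
                                "value": rng.normal(),
                            }
                        )
        rep = hemisphere_group_screen(pd.DataFrame(rows), ["MD", "thickness"])
        assert rep["average_hemispheres"].all()


class TestVertexwise:
    def make_inputs(self, rng, P=80, V=50):
        cov = pd.DataFrame(
            {
                "age": rng.uniform(55, 90, P),
                "sex": rng.choice(["F", "M"], P),
                "group": rng.choice(["AD", "MCI", "CN"], P),
            }
        )
        thickness = rng.normal(2.0, 0.1, (P, V))
        return cov, thickness

    def test_strong_age_effect_limit(self):
        rng = np.random.default_rng(17)
        cov, th = self.make_inputs(rng)
        maps = 0.1 * cov["age"].to_numpy()[:, None] + rng.normal(0, 1e-4, (80, 50))
        cm = vertexwise_contrast(maps, cov, th, "age")
        assert np.all(cm.t[cm.valid] > 100.0)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(18)
        cov, th = self.make_inputs(rng, P=60, V=500)
        maps = rng.normal(size=(60, 500))
        cm = vertexwise_contrast(maps, cov, th, "age")
        crit = stats.t.ppf(0.975, 60 - 5)
        rate = np.mean(np.abs(cm.t[cm.valid]) > crit)
        assert 0.03 <= rate <= 0.07

    def test_matches_per_vertex_oracle(self):
        rng = np.random.default_rng(19)
        cov, th = self.make_inputs(rng, P=40, V=10)
        maps = rng.normal(size=(40, 10))
        cm = vertexwise_contrast(maps, cov, th, "age")
        sex = (cov["sex"] == "M").to_numpy(float)
        for v in range(10):
            X = np.column_stack(
                [np.ones(40), cov["age"], th[:, v], sex, cov["age"] * sex]
            )
            beta, rss, df = oracles.ols_normal_equations(X, maps[:, v])
            se = np.sqrt(rss / df * np.linalg.inv(X.T @ X)[1, 1])
            assert cm.t[v] == pytest.approx(beta[1] / se, abs=1e-8)

    def test_group_contrast_reference_is_ad(self):
        rng = np.random.default_rng(20)
        cov, th = self.make_inputs(rng, P=90, V=5)
        shift = np.select(
            [cov["group"] == "MCI", cov["group"] == "CN"], [1.0, 2.0], 0.0
        )
        maps = shift[:, None] + rng.normal(0, 0.1, (90, 5))
        mci = vertexwise_contrast(maps, cov, th, "group:MCI")
        cn = vertexwise_contrast(maps, cov, th, "group:CN")
        assert np.all(mci.t[mci.valid] > 3)
        assert np.all(cn.t[cn.valid] > mci.t[cn.valid])

    def test_constant_thickness_vertex_invalid(self):
        rng = np.random.default_rng(21)
        cov, th = self.make_inputs(rng, P=40, V=3)
        th[:, 1] = 2.0  # exactly collinear with the intercept
        maps = rng.normal(size=(40, 3))
        cm = vertexwise_contrast(maps, cov, th, "age")
        assert not cm.valid[1]
        assert cm.valid[0] and cm.valid[2]
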
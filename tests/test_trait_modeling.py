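"""OLS, forward selection, residual ANOVA/Tukey, RM-ANOVA with GG, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenorover import synthetic_field as synth
from phenorover import trait_modeling as tm


def _random_design(rng, n=40, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = rng.normal(size=p)
    y = 1.0 + X.to_numpy() @ beta + rng.normal(0, 0.5, n)
    return X, y


class TestFitOLS:
    def test_exact_linear_recovered(self, rng):
        X = pd.DataFrame({"x": np.arange(10.0)})
        y = 2.0 + 3.0 * X["x"]
        fit = tm.fit_ols(X, y)
        assert fit.r2 == pytest.approx(1.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        assert fit.coef["x"] == pytest.approx(3.0)

    def test_intercept_only_fits_mean(self, rng):
        y = rng.normal(5, 1, 20)
        fit = tm.fit_ols(pd.DataFrame(index=range(20)), y)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.fitted, y.mean())

    def test_matches_normal_equations_oracle(self, rng):
        X, y = _random_design(rng)
        fit = tm.fit_ols(X, y)
        A = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.coef.to_numpy(), beta, atol=1e-8)

    def test_rank_deficiency_rejected(self, rng):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(np.linalg.LinAlgError):
            tm.fit_ols(X, rng.normal(size=10))

    def test_more_columns_than_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 6)))
        X.columns = [str(c) for c in X.columns]
        with pytest.raises(ValueError):
            tm.fit_ols(X, rng.normal(size=5))

    def test_sequential_ss_sums_to_explained_ss(self, rng):
        X, y = _random_design(rng)
        blocks = [("b1", ["x0", "x1"]), ("b2", ["x2"]), ("b3", ["x3"])]
        fit = tm.fit_ols(X[["x0", "x1", "x2", "x3"]], y, blocks=blocks)
        assert sum(fit.seq_ss.values()) == pytest.approx(fit.sst - fit.sse)

    def test_adding_a_column_never_decreases_r2(self, rng):
        X, y = _random_design(rng, n=50, p=3)
        base = tm.fit_ols(X[["x0", "x1"]], y).r2
        for _ in range(10):
            X2 = X[["x0", "x1"]].copy()
            X2["junk"] = rng.normal(size=50)
            assert tm.fit_ols(X2, y).r2 >= base - 1e-12


class TestForwardSelect:
    def _dates(self, rng, beta=2.0, n=60, n_dates=3, noise=0.5):
        per_date = {}
        for d in range(n_dates):
            X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
            y = beta * X["x1"] + rng.normal(0, noise, n)
            per_date[f"d{d}"] = (X, y)
        return per_date

    def test_signal_variable_selected_first(self, rng):
        per_date = self._dates(rng)
        cands = [tm.Candidate("x1", ("x1",)), tm.Candidate("x2", ("x2",))]
        sel = tm.forward_select(per_date, cands)
        assert sel.selected_names[0] == "x1"

    def test_infinite_tolerance_selects_nothing(self, rng):
        per_date = self._dates(rng)
        cands = [tm.Candidate("x1", ("x1",))]
        sel = tm.forward_select(per_date, cands, tolerance=np.inf)
        assert sel.selected == []
        assert sel.mean_r2 == 0.0

    def test_single_date_reduces_to_plain_greedy(self, rng):
        per_date = self._dates(rng, n_dates=1)
        cands = [tm.Candidate("x1", ("x1",)), tm.Candidate("x2", ("x2",))]
        sel = tm.forward_select(per_date, cands)
        (X, y) = per_date["d0"]
        assert sel.mean_r2 == pytest.approx(
            tm.fit_ols(X[["x1"]], y).r2 if sel.selected_names == ["x1"]
            else tm.fit_ols(X[list(sel.selected_names)], y).r2)

    def test_trace_mean_r2_non_decreasing(self, rng):
        per_date = {f"d{d}": (pd.DataFrame(rng.normal(size=(60, 5)),
                                           columns=list("abcde")),
                              pd.Series(rng.normal(size=60)))
                    for d in range(3)}
        # add signal on two columns
        for d, (X, y) in per_date.items():
            per_date[d] = (X, y + 2 * X["a"] - X["b"])
        cands = [tm.Candidate(c, (c,)) for c in "abcde"]
        sel = tm.forward_select(per_date, cands, tolerance=0.0)
        assert sel.trace["mean_r2"].is_monotonic_increasing
        assert len(sel.selected) <= len(cands)

    def test_scheme_exclusivity(self, rng):
        n = 80
        base = rng.normal(size=n)
        X = pd.DataFrame({"wx:temp[a]": base,
                          "wx:temp[b]": base + rng.normal(0, 0.1, n),
                          "other": rng.normal(size=n)})
        y = 3 * base + rng.normal(0, 0.3, n)
        per_date = {"d0": (X, pd.Series(y))}
        cands = tm.build_candidates(list(X.columns))
        sel = tm.forward_select(per_date, cands)
        chosen = [c for c in sel.selected_names if c.startswith("wx:temp")]
        assert len(chosen) == 1  # one scheme per weather variable

    def test_constant_candidate_skipped_with_warning(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=30), "flat": np.ones(30)})
        y = pd.Series(2 * X["x1"] + rng.normal(0, 0.1, 30))
        cands = [tm.Candidate("flat", ("flat",)), tm.Candidate("x1", ("x1",))]
        sel = tm.forward_select({"d0": (X, y)}, cands)
        assert sel.selected_names == ["x1"]

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.forward_select({}, [tm.Candidate("x", ("x",))])
        with pytest.raises(ValueError):
            tm.forward_select({"d": (pd.DataFrame({"x": [1.0, 2.0]}),
                                     pd.Series([1.0, 2.0]))}, [])


class TestBuildCandidates:
    def test_variety_dummies_form_one_block(self):
        cols = ["row_spacing_mm", "soil:shallow:N", "wx:temp_c[a]",
                "wx:temp_c[b]", "variety:B", "variety:C"]
        cands = tm.build_candidates(cols)
        names = [c.name for c in cands]
        assert "variety" in names
        variety = next(c for c in cands if c.name == "variety")
        assert variety.columns == ("variety:B", "variety:C")
        temp_a = next(c for c in cands if c.name == "wx:temp_c[a]")
        assert temp_a.exclusive_group == "temp_c"


class TestResidualAnovaTukey:
    def test_degenerate_zero_variance_flagged(self):
        resid = np.zeros(12)
        groups = np.repeat(["a", "b", "c"], 4)
        anova, tukey = tm.residual_anova_tukey(resid, groups)
        assert anova.degenerate
        assert np.isnan(anova.F)
        assert len(tukey) == 0

    def test_two_groups_agree_with_pooled_t_test(self, rng):
        # for k = 2 the studentized range collapses to q = sqrt(2)*|t|
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(rng.uniform(-2, 2), 1, 8)
            resid = np.concatenate([a, b])
            groups = np.repeat(["g1", "g2"], 8)
            _, tukey = tm.residual_anova_tukey(resid, groups, alpha=0.05)
            t, p = stats.ttest_ind(a, b)
            assert bool(tukey["reject"].iloc[0]) == (p < 0.05)
            assert tukey["p_adj"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_small_variety_excluded(self, rng):
        resid = rng.normal(size=9)
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"])  # c has 1 obs
        anova, tukey = tm.residual_anova_tukey(resid, groups)
        assert set(tukey["group1"]) | set(tukey["group2"]) == {"a", "b"}

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            tm.residual_anova_tukey(rng.normal(size=4), ["a"] * 4)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        # independent route: statsmodels' pairwise_tukeyhsd on the same data
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        resid = rng.normal(size=33) + np.repeat(rng.normal(0, 1.0, 11), 3)
        groups = np.repeat([f"v{i:02d}" for i in range(11)], 3)
        _, tukey = tm.residual_anova_tukey(resid, groups, alpha=0.05)
        ref = pairwise_tukeyhsd(resid, groups, alpha=0.05)
        np.testing.assert_allclose(tukey["meandiff"], ref.meandiffs, atol=1e-10)
        np.testing.assert_allclose(tukey["lower"], ref.confint[:, 0], atol=1e-8)
        np.testing.assert_allclose(tukey["upper"], ref.confint[:, 1], atol=1e-8)
        np.testing.assert_allclose(tukey["p_adj"], ref.pvalues, atol=1e-6)
        assert (tukey["reject"].to_numpy() == ref.reject).all()

    def test_anova_f_matches_scipy(self, rng):
        groups = np.repeat([f"v{i}" for i in range(5)], 6)
        resid = rng.normal(size=30) + np.repeat(rng.normal(0, 0.5, 5), 6)
        anova, _ = tm.residual_anova_tukey(resid, groups)
        F, p = stats.f_oneway(*[resid[groups == g] for g in np.unique(groups)])
        assert anova.F == pytest.approx(F)
        assert anova.p == pytest.approx(p)


class TestGGEpsilon:
    def test_k2_is_exactly_one(self, rng):
        for _ in range(10):
            A = rng.normal(size=(2, 2))
            assert tm.gg_epsilon(A @ A.T) == 1.0

    def test_bounds_on_random_covariances(self, rng):
        for k in (3, 4, 6):
            for _ in range(20):
                A = rng.normal(size=(k, k + 2))
                eps = tm.gg_epsilon(A @ A.T)
                assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_compound_symmetry_gives_one(self):
        k, rho = 4, 0.6
        S = rho * np.ones((k, k)) + (1 - rho) * np.eye(k)
        assert tm.gg_epsilon(S) == pytest.approx(1.0)

    def test_rank_one_centered_covariance_hits_lower_bound(self):
        v = np.array([1.0, -1.0, 0.0, 0.0])  # centered: double-centering keeps rank 1
        S = np.outer(v, v)
        assert tm.gg_epsilon(S) == pytest.approx(1.0 / 3.0)


class TestRMAnova:
    def _data(self, rng, g=5, r=4, k=4, interaction=0.0):
        n = g * r
        variety = np.repeat([f"v{i}" for i in range(g)], r)
        Y = (rng.normal(0, 1, (n, 1))
             + np.linspace(0, 2, k)
             + rng.normal(0, 0.5, g)[np.repeat(np.arange(g), r), None]
             + rng.normal(0, 1, (n, k)))
        if interaction:
            Y += interaction * np.outer(np.repeat(np.arange(g), r), np.arange(k))
        wide = pd.DataFrame(Y, columns=[f"d{j}" for j in range(k)])
        return wide, pd.Series(variety)

    def test_k2_epsilon_exactly_one(self, rng):
        wide, variety = self._data(rng, k=2)
        assert tm.rm_anova_gg(wide, variety).epsilon == 1.0

    def test_unbalanced_design_rejected(self, rng):
        wide, variety = self._data(rng)
        with pytest.raises(ValueError, match="nbalanced"):
            tm.rm_anova_gg(wide.iloc[1:], variety.iloc[1:])

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        # interaction-free data: with distinct group time-profiles the two
        # epsilon conventions (pooled within-group vs grand covariance)
        # legitimately diverge, while F and p always agree exactly
        wide, variety = self._data(rng, interaction=0.0)
        res = tm.rm_anova_gg(wide, variety)
        long = wide.copy()
        long["subject"] = range(len(wide))
        long["variety"] = variety.to_numpy()
        long = long.melt(id_vars=["subject", "variety"], var_name="time",
                         value_name="y")
        out = pg.mixed_anova(data=long, dv="y", within="time",
                             subject="subject", between="variety").set_index("Source")
        assert res.effects["variety"].F == pytest.approx(out.loc["variety", "F"])
        assert res.effects["time"].F == pytest.approx(out.loc["time", "F"])
        assert res.effects["variety_x_time"].F == pytest.approx(
            out.loc["Interaction", "F"])
        assert res.effects["time"].p == pytest.approx(out.loc["time", "p_unc"])
        # epsilon: on within-variety-centered data the grand-covariance and
        # pooled-covariance conventions coincide (epsilon is scale invariant)
        centered = wide - wide.groupby(variety.to_numpy()).transform("mean")
        assert res.epsilon == pytest.approx(float(pg.epsilon(centered,
                                                             correction="gg")),
                                            rel=1e-9)

    def test_compound_symmetry_epsilon_near_one(self, rng):
        g, r, k = 11, 6, 4
        n = g * r
        variety = np.repeat([f"v{i}" for i in range(g)], r)
        subj = rng.normal(0, 1.0, (n, 1))  # CS: equal covariance between dates
        Y = subj + rng.normal(0, 1.0, (n, k))
        res = tm.rm_anova_gg(pd.DataFrame(Y), pd.Series(variety))
        assert abs(res.epsilon - 1.0) < 0.15

    def test_dominant_eigenvalue_epsilon_near_lower_bound(self, rng):
        g, r, k = 4, 30, 4
        n = g * r
        variety = np.repeat([f"v{i}" for i in range(g)], r)
        f = rng.normal(0, 3.0, n)
        pattern = np.array([1.0, -1.0, 0.5, -0.5])
        Y = np.outer(f, pattern) + rng.normal(0, 0.05, (n, k))
        res = tm.rm_anova_gg(pd.DataFrame(Y), pd.Series(variety))
        assert res.epsilon < 1.0 / (k - 1) + 0.05


class TestEffectSizes:
    def test_pure_variety_signal(self):
        # management balanced within varieties: orthogonal to the signal,
        # so the sequential partition cannot hand it variety variance
        rng = np.random.default_rng(404)
        n = 40
        variety = np.repeat(["a", "b", "c", "d"], 10)
        X = pd.DataFrame({
            "wx:temp[a]": rng.normal(size=n),
            "row_spacing_mm": np.tile([559.0, 762.0], n // 2),
            "variety:b": (variety == "b").astype(float),
            "variety:c": (variety == "c").astype(float),
            "variety:d": (variety == "d").astype(float),
        })
        y = pd.Series(variety).map({"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0})
        cmap = {"wx:temp[a]": "Environment", "row_spacing_mm": "Management",
                "variety:b": "Variety", "variety:c": "Variety",
                "variety:d": "Variety"}
        part = tm.effect_size_partition(X, y, cmap)
        assert part["Variety"] > 95.0
        assert part["Error"] < 1.0

    def test_percentages_sum_to_100(self, rng):
        X = pd.DataFrame({"wx:a[a]": rng.normal(size=30),
                          "row_spacing_mm": rng.normal(size=30),
                          "variety:b": rng.integers(0, 2, 30).astype(float)})
        y = rng.normal(size=30)
        cmap = {"wx:a[a]": "Environment", "row_spacing_mm": "Management",
                "variety:b": "Variety"}
        part = tm.effect_size_partition(X, y, cmap)
        assert sum(part.values()) == pytest.approx(100.0)

    def test_pure_noise_mostly_error(self, rng):
        n = 200
        X = pd.DataFrame({"wx:a[a]": rng.normal(size=n),
                          "m": rng.normal(size=n)})
        y = rng.normal(size=n)
        part = tm.effect_size_partition(
            X, y, {"wx:a[a]": "Environment", "m": "Management"})
        assert part["Error"] > 90.0

    def test_unmapped_predictor_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=10)})
        with pytest.raises(ValueError, match="unmapped|x"):
            tm.effect_size_partition(X, rng.normal(size=10), {})


class TestSelectionRecoveryHarness:
    def test_feature_tables_share_columns_across_dates(self, small_layout):
        truth = synth.default_truth(small_layout, seed=1)
        tables = synth.selection_feature_table(truth, small_layout)
        cols = [tuple(X.columns) for X in tables.values()]
        assert all(c == cols[0] for c in cols)
        assert any(c.startswith("variety:") for c in cols[0])
        assert "wx:temp_c[a]" in cols[0]

    def test_three_predictor_recovery_single_seed(self, small_layout):
        lay = synth.gen_layout(6, 8, 15.0, synth.DEFAULT_VARIETIES[:6], seed=3)
        true = ["soil:shallow:organic_matter", "wx:temp_c[a]", "row_spacing_mm"]
        per_date, _ = synth.make_selection_problem(lay, true, snr=3.0, seed=3)
        cands = tm.build_candidates(list(next(iter(per_date.values()))[0].columns))
        sel = tm.forward_select(per_date, cands)
        assert set(true) <= set(sel.selected_names)
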
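import logging

import numpy as np
import pandas as pd
import pytest

from reefcomposite.seascape_models import (
    DegenerateModelError,
    MixedModelSelection,
    ModelSelection,
    colinearity_screen,
    enumerate_candidates,
    exhaustive_model_selection,
    fit_mixed_aicc,
    fit_ols_aicc,
    lgm_loss,
    quadratic_fit,
    trait_models,
)


class TestLGMLoss:
    @pytest.mark.parametrize("lgm,present,expected", [
        (120.0, 120.0, 0.0),
        (0.0, 50.0, 1.0),
        (30.0, 120.0, 0.75),
    ])
    def test_values(self, lgm, present, expected):
        assert lgm_loss(lgm, present) == pytest.approx(expected)

    def test_present_area_must_be_positive(self):
        with pytest.raises(ValueError):
            lgm_loss(10.0, 0.0)

    def test_excess_lgm_area_clamped_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert lgm_loss(150.0, 100.0) == 0.0
        assert any("clamped" in r.message for r in caplog.records)


class TestOLSAICc:
    def test_intercept_only_hand_formula(self):
        # y = 1..5: RSS = 10, K = 2;
        # AICc = n ln(RSS/n) + n ln(2pi) + n + 2K + 2K(K+1)/(n-K-1)
        f = fit_ols_aicc(np.array([1.0, 2, 3, 4, 5]), None)
        n, k, rss = 5, 2, 10.0
        expected = (n * np.log(rss / n) + n * np.log(2 * np.pi) + n
                    + 2 * k + 2 * k * (k + 1) / (n - k - 1))
        assert f.k == 2
        assert f.aicc == pytest.approx(expected, abs=1e-10)
        assert f.aicc == pytest.approx(27.655, abs=1e-3)

    def test_perfect_fit_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        y = 2 * X["x"] + 1
        with pytest.raises(DegenerateModelError, match="perfect"):
            fit_ols_aicc(y, X)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        X = pd.DataFrame({"a": x - x.mean(), "b": 2 * (x - x.mean())})
        with pytest.raises(DegenerateModelError, match="rank"):
            fit_ols_aicc(rng.normal(size=8), X)

    def test_too_small_sample_rejected(self):
        with pytest.raises(DegenerateModelError, match="small"):
            fit_ols_aicc(np.array([1.0, 2, 3]), pd.DataFrame({"x": [1.0, 2, 3]}))

    def test_adjusted_r2_standard_formula(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        y = X["x"] + rng.normal(size=20)
        f = fit_ols_aicc(y, X)
        assert f.adj_r2 == pytest.approx(1 - (1 - f.r2) * 19 / 18, abs=1e-12)


class TestExhaustiveSelection:
    def test_single_predictor_single_candidate_full_weight(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=13)})
        y = X["x"] * 0.5 + rng.normal(size=13)
        res = exhaustive_model_selection(y, X, max_terms=3)
        cand = res.table[~res.table["reference"]]
        assert len(cand) == 1
        assert cand["w"].iloc[0] == pytest.approx(1.0)
        assert res.table["delta_aicc"].min() == 0.0

    def test_akaike_weights_at_delta_two(self):
        # two candidates at ΔAICc 0 and 2 -> weights 0.731 / 0.269
        w0 = 1 / (1 + np.exp(-1.0))
        assert w0 == pytest.approx(0.731, abs=1e-3)
        rel = np.exp([-0.0, -1.0])
        w = rel / rel.sum()
        assert w[0] == pytest.approx(0.731, abs=1e-3)
        assert w[1] == pytest.approx(0.269, abs=1e-3)

    def test_weights_sum_to_one_and_deltas_ordered(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(13, 4)), columns=list("abcd"))
        y = X["a"] * 0.8 + rng.normal(size=13)
        res = exhaustive_model_selection(y, X, max_terms=3)
        cand = res.table[~res.table["reference"]]
        assert cand["w"].sum() == pytest.approx(1.0)
        assert (res.table["delta_aicc"].diff().dropna() >= -1e-12).all()
        assert res.table["delta_aicc"].iloc[0] == 0.0
        n_expected = 4 + 6 + 4  # subsets of size 1..3 of 4 predictors
        assert len(cand) == n_expected

    def test_candidate_enumeration_counts(self):
        assert len(enumerate_candidates(list("abcde"), 3)) == 1 + 5 + 10 + 10

    def test_growing_pool_leaves_existing_aicc_unchanged(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(13, 3)), columns=list("abc"))
        y = X["a"] * 0.8 + rng.normal(size=13)
        res3 = exhaustive_model_selection(y, X, max_terms=2)
        X4 = X.copy()
        X4["noise"] = rng.normal(size=13)
        res4 = exhaustive_model_selection(y, X4, max_terms=2)
        for terms, fit in res3.fits.items():
            assert res4.fits[terms].aicc == pytest.approx(fit.aicc, abs=1e-10)

    def test_recovery_of_true_driver(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(40):
            X = pd.DataFrame(rng.normal(size=(13, 4)),
                             columns=["habitat", "b", "c", "d"])
            y = 1.0 * X["habitat"] + rng.normal(scale=0.8, size=13)
            res = exhaustive_model_selection(y, X, max_terms=3)
            hits += res.term_in_top_set("habitat")
        assert hits / 40 >= 0.9

    def test_sign_filter_drops_wrong_sign_models(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"up": rng.normal(size=15), "down": rng.normal(size=15)})
        y = X["up"] - X["down"] + rng.normal(scale=0.5, size=15)
        res = ModelSelection(y, X, sign_hypotheses={"up": 1, "down": 1}).fit(
            sign_filter=True)
        assert all("down" not in t for t in res.fits if t)


class TestMixedModels:
    def make_records(self, n_groups=8, n_islands=10, group_sd=0.7, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n_islands)
        rows = []
        offsets = rng.normal(0, group_sd, n_groups)
        for g in range(n_groups):
            for i in range(n_islands):
                rows.append({"group": f"g{g}", "island": i, "x": x[i],
                             "ar": 3 + 0.8 * x[i] + offsets[g]
                             + rng.normal(0, 0.5)})
        return pd.DataFrame(rows), offsets

    def test_zero_group_variance_limit_matches_pooled_ols(self):
        records, _ = self.make_records(group_sd=0.0, seed=1)
        mixed = fit_mixed_aicc(records, ["x"])
        ols = fit_ols_aicc(records["ar"], records[["x"]])
        assert mixed.coefficients["x"] == pytest.approx(
            ols.coefficients["x"], abs=0.02)
        assert mixed.coefficients["intercept"] == pytest.approx(
            ols.coefficients["intercept"], abs=0.02)

    def test_group_intercept_blup_signs_recovered(self):
        records, offsets = self.make_records(group_sd=1.5, seed=2)
        fit = fit_mixed_aicc(records, ["x"])
        signs = [np.sign(fit.random_effects[f"g{g}"]) == np.sign(offsets[g])
                 for g in range(len(offsets))]
        assert np.mean(signs) >= 0.9

    def test_k_counts_both_variances(self):
        records, _ = self.make_records(seed=3)
        fit = fit_mixed_aicc(records, ["x"])
        assert fit.k == 2 + 2  # intercept + slope + resid var + group var

    def test_same_enumeration_as_ols_path(self):
        records, _ = self.make_records(seed=4)
        records["z"] = np.random.default_rng(0).normal(size=len(records))
        mres = MixedModelSelection(records, ["x", "z"], max_terms=2).fit()
        ols_terms = set(enumerate_candidates(["x", "z"], 2))
        assert set(mres.fits) | set(mres.skipped) == ols_terms

    def test_null_group_label_rejected(self):
        records, _ = self.make_records(seed=5)
        records.loc[0, "group"] = None
        with pytest.raises(ValueError, match="non-null"):
            fit_mixed_aicc(records, ["x"])


class TestColinearityScreen:
    def exact_corr_data(self, target, n=60, seed=0):
        """Columns whose empirical correlation matrix equals ``target``."""
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(n, target.shape[0]))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        L = np.linalg.cholesky(target)
        data = q @ L.T
        return pd.DataFrame(data / data.std(axis=0, ddof=1),
                            columns=list("abc")[: target.shape[0]])

    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=20)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=20)
        retained, corr = colinearity_screen(df, ["a", "b", "c"])
        assert len(retained) == 2 and "c" in retained

    def test_postcondition_max_pairwise_below_threshold(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(25, 5)), columns=list("abcde"))
        df["f"] = df["a"] * 0.9 + rng.normal(scale=0.3, size=25)
        retained, corr = colinearity_screen(df, list("abcdef"), threshold=0.7)
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0)
        assert sub.max() < 0.7

    def test_greedy_rule_hand_traced(self):
        # r(a,b)=0.9, r(a,c)=0.8, r(b,c)=0.5 (a feasible correlation matrix):
        # a has the larger mean |r| (0.85 vs 0.70 / 0.65) and is dropped
        # first; the surviving pair (b,c) at 0.5 sits below the threshold.
        target = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        df = self.exact_corr_data(target)
        corr = df.corr()
        assert corr.loc["a", "b"] == pytest.approx(0.9, abs=1e-9)
        retained, _ = colinearity_screen(df, ["a", "b", "c"], threshold=0.7)
        assert retained == ["b", "c"]


class TestQuadraticFit:
    def test_pure_quadratic_is_exact(self):
        x = np.linspace(19, 28, 10)
        y = (x - x.mean()) ** 2
        fit = quadratic_fit(y, x)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients["x2"] > 0

    def test_constant_x_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            quadratic_fit(np.arange(5.0), np.full(5, 2.0))

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(300):
            x = np.linspace(0, 1, 13)
            y = rng.normal(size=13)
            ps.append(quadratic_fit(y, x).p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_margins_scenario_gives_positive_curvature(self):
        from reefcomposite import composite_ar, generate_scenario, species_island_ar
        seascape, table, traits, truth = generate_scenario("habitat_driver",
                                                           seed=21)
        ar = species_island_ar(table)
        comp = composite_ar(ar, seed=21)
        s = comp.series()
        fit = quadratic_fit(s.to_numpy(),
                            seascape.data.loc[s.index, "latitude"].to_numpy())
        assert fit.coefficients["x2"] > 0


class TestTraitModels:
    def traits_frame(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "species": [f"sp{i:02d}" for i in range(n)],
            "fish": rng.integers(0, 2, n),
            "theta_ST": rng.uniform(0, 0.4, n),
            "pld_log": rng.normal(3.5, 0.7, n),
        })

    def test_binary_trait_response_recovered_exactly(self):
        traits = self.traits_frame(seed=1)
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(
            {"r_coral_cover": traits["fish"].to_numpy() * 0.6 - 0.3
             + rng.normal(0, 0.05, len(traits))},
            index=traits["species"])
        res = trait_models(prof, traits, drivers=["coral_cover"],
                           trait_columns=["fish", "theta_ST", "pld_log"],
                           max_terms=2)["coral_cover"]
        assert "fish" in res.best.terms
        assert res.best.coefficients["fish"] > 0
        assert res.table[res.table["model"] == "fish"]["delta_aicc"].iloc[0] < 2.0

    def test_theta_st_effect_in_top_set_with_high_probability(self):
        hits = 0
        for seed in range(40):
            traits = self.traits_frame(seed=seed)
            rng = np.random.default_rng(seed + 1000)
            prof = pd.DataFrame(
                {"r_habitat": traits["theta_ST"].to_numpy() * 5 - 1
                 + rng.normal(0, 0.35, len(traits))},
                index=traits["species"])
            res = trait_models(prof, traits, drivers=["r_habitat"],
                               trait_columns=["fish", "theta_ST", "pld_log"],
                               max_terms=2)["r_habitat"]
            hits += res.term_in_top_set("theta_ST")
        assert hits / 40 >= 0.9

    def test_shuffled_response_rarely_beats_intercept(self):
        wins = 0
        for seed in range(40):
            traits = self.traits_frame(seed=seed)
            rng = np.random.default_rng(seed + 2000)
            prof = pd.DataFrame({"r_x": rng.normal(0, 0.3, len(traits))},
                                index=traits["species"])
            res = trait_models(prof, traits, drivers=["r_x"],
                               trait_columns=["fish", "theta_ST", "pld_log"],
                               max_terms=2)["r_x"]
            wins += res.reference_delta >= 2.0
        assert wins / 40 <= 0.35

    def test_partial_mode_residualizes_covariates(self):
        traits = self.traits_frame(seed=3)
        traits["n_islands"] = np.arange(len(traits))
        rng = np.random.default_rng(3)
        # response driven purely by the sampling covariate
        prof = pd.DataFrame(
            {"r_y": 0.02 * traits["n_islands"].to_numpy()
             + rng.normal(0, 0.02, len(traits))},
            index=traits["species"])
        res = trait_models(prof, traits, drivers=["r_y"],
                           trait_columns=["fish", "theta_ST", "pld_log"],
                           covariates=["n_islands"], max_terms=2)["r_y"]
        assert res.reference_delta < 2.0  # nothing left for traits to explain
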
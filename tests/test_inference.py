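import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ehc_access.accessibility import DENSELY_POPULATED, RURAL, URBAN
from ehc_access.inference import (
    ModelSpec,
    anova_by_area_type,
    build_design,
    correlation_rt_tt,
    fit_disparity_models,
    fit_nb,
    pearson_screen,
)


class TestPearsonScreen:
    def test_duplicated_column_is_flagged_and_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        retained, flagged = pearson_screen(df)
        assert retained == ["a", "c"]
        assert flagged[0][:2] == ("a", "b")
        assert flagged[0][2] == pytest.approx(1.0)

    def test_independent_columns_pass(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        retained, flagged = pearson_screen(df)
        assert retained == ["a", "b"]
        assert flagged == []

    def test_r_matches_hand_computation_on_five_rows(self):
        # x = 1..5, y = (2,4,5,4,5): r = 6 / sqrt(10*6) = sqrt(0.6)
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 4, 5, 4, 5]})
        _, flagged = pearson_screen(df, threshold=0.5)
        assert flagged[0][2] == pytest.approx(math.sqrt(0.6), abs=1e-12)

    def test_priority_controls_which_member_drops(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(scale=1e-3, size=50)})
        retained, _ = pearson_screen(df, priority=["b", "a"])
        assert retained == ["b"]

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        retained, flagged = pearson_screen(df)
        assert retained == ["b"]
        assert flagged[0][0] == "a" and math.isnan(flagged[0][2])


class TestCorrelationRtTt:
    def test_perfect_linear_relation(self):
        df = pd.DataFrame({"rt_min": [1.0, 2, 3, 4], "tt_min": [2.0, 4, 6, 8]})
        r, p = correlation_rt_tt(df)
        assert r == pytest.approx(1.0)

    def test_independent_measures_have_small_r(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"rt_min": rng.normal(size=1000), "tt_min": rng.normal(size=1000)})
        r, p = correlation_rt_tt(df)
        assert abs(r) < 0.1
        assert p > 0.05

    def test_matches_manual_formula_on_six_pairs(self):
        rt = np.array([5.0, 8.0, 11.0, 7.0, 13.0, 6.0])
        tt = np.array([12.0, 15.0, 22.0, 13.0, 25.0, 14.0])
        df = pd.DataFrame({"rt_min": rt, "tt_min": tt})
        r, _ = correlation_rt_tt(df)
        # textbook formula written out
        num = ((rt - rt.mean()) * (tt - tt.mean())).sum()
        den = math.sqrt(((rt - rt.mean()) ** 2).sum() * ((tt - tt.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_raises(self):
        df = pd.DataFrame({"rt_min": [1.0, 1.0, 1.0], "tt_min": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            correlation_rt_tt(df)


class TestAnova:
    def test_identical_groups_give_zero_f_unit_p(self):
        vals = [1.0, 2.0, 3.0] * 3
        types = [URBAN] * 3 + [DENSELY_POPULATED] * 3 + [RURAL] * 3
        res = anova_by_area_type(vals, types)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0) for _, p in res.tukey.values())

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 40), rng.normal(0.7, 1, 35)
        res = anova_by_area_type(np.concatenate([a, b]), ["u"] * 40 + ["r"] * 35)
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t ** 2, abs=1e-8)

    def test_hand_worked_twelve_observation_example(self):
        """Three groups of four with F = (104/3/2)/(15/9) = 10.4 exactly."""
        groups = {"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5], "c": [5.0, 6, 7, 8]}
        vals = sum(groups.values(), [])
        types = [g for g in groups for _ in range(4)]
        res = anova_by_area_type(vals, types)
        assert res.F == pytest.approx(10.4, abs=1e-8)
        assert (res.df_between, res.df_within) == (2, 9)
        means = dict(zip(res.group_stats.group, res.group_stats["mean"]))
        assert means == {"a": 2.5, "b": 3.5, "c": 6.5}
        # Tukey p for pair (a, c) from the studentized range distribution
        msw = 15.0 / 9.0
        q = abs(2.5 - 6.5) / math.sqrt(msw / 2 * (1 / 4 + 1 / 4))
        expected_p = stats.studentized_range.sf(q, 3, 9)
        diff, p = res.tukey[("a", "c")]
        assert diff == pytest.approx(-4.0)
        assert p == pytest.approx(expected_p, abs=1e-8)

    def test_small_group_error_names_group(self):
        with pytest.raises(ValueError, match="lonely"):
            anova_by_area_type([1.0, 2.0, 3.0], ["a", "a", "lonely"])


def _nb_sim(rng, n, beta=(2.0, 0.8, -0.9), alpha=0.2):
    X = pd.DataFrame({
        "const": np.ones(n),
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
    })
    mu = np.exp(X.to_numpy() @ np.asarray(beta))
    lam = rng.gamma(1.0 / alpha, mu * alpha)
    return X, rng.poisson(lam).astype(float)


class TestFitNB:
    def test_intercept_only_constant_response(self):
        X = pd.DataFrame({"const": np.ones(40)})
        res = fit_nb(X, np.full(40, 7.0))
        assert res.estimate("const") == pytest.approx(np.log(7.0), abs=1e-6)
        assert res.alpha < 1e-6  # dispersion collapses to the Poisson boundary

    def test_poisson_limit_oracle(self):
        rng = np.random.default_rng(5)
        n = 1000
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n)})
        y = rng.poisson(np.exp(1.0 + 0.5 * X.x))
        res = fit_nb(X, y, alpha=1e-8)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        for i, term in enumerate(X.columns):
            assert res.estimate(term) == pytest.approx(pois.params.iloc[i], abs=1e-4)

    def test_matches_full_ml_negative_binomial(self):
        """Cross-check against statsmodels' joint-ML NB2 estimator."""
        rng = np.random.default_rng(6)
        X, y = _nb_sim(rng, 2000)
        ours = fit_nb(X, y)
        full = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0, maxiter=200)
        for i, term in enumerate(X.columns):
            assert ours.estimate(term) == pytest.approx(full.params.iloc[i], abs=1e-4)
        assert ours.alpha == pytest.approx(full.params.iloc[-1], rel=1e-3)
        assert ours.log_likelihood == pytest.approx(full.llf, abs=1e-4)

    def test_aic_bic_identities(self):
        rng = np.random.default_rng(7)
        X, y = _nb_sim(rng, 500)
        res = fit_nb(X, y)
        k = X.shape[1] + 1
        assert res.aic == 2 * k - 2 * res.log_likelihood
        assert res.bic == k * math.log(res.n) - 2 * res.log_likelihood

    def test_rank_deficient_design_names_terms(self):
        X = pd.DataFrame({"const": np.ones(30), "a": np.arange(30.0)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_nb(X, np.ones(30))

    def test_negative_response_rejected(self):
        X = pd.DataFrame({"const": np.ones(5)})
        with pytest.raises(ValueError):
            fit_nb(X, [-1.0, 0, 1, 2, 3])

    def test_income_rescaling_only_rescales_income(self):
        """Rescaling a covariate by 1/1000 multiplies its coefficient by
        1000 and leaves every other estimate essentially unchanged (why a
        raw-currency income coefficient prints as 0.000)."""
        rng = np.random.default_rng(8)
        n = 800
        income = rng.normal(300_000, 30_000, size=n)
        X = pd.DataFrame({"const": np.ones(n), "income": income, "x": rng.normal(size=n)})
        mu = np.exp(1.0 + 1e-6 * (income - 300_000) + 0.3 * X.x)
        y = rng.poisson(rng.gamma(10.0, mu / 10.0))
        r_raw = fit_nb(X, y)
        X2 = X.assign(income=X.income / 1000.0)
        r_scaled = fit_nb(X2, y)
        assert r_scaled.estimate("income") == pytest.approx(1000 * r_raw.estimate("income"), rel=1e-6)
        for term in ("const", "x"):
            assert abs(r_scaled.estimate(term) - r_raw.estimate(term)) < 1e-8


def _areas_frame(n, rng, rural_share=0.3):
    n_rural = int(n * rural_share)
    types = np.array([RURAL] * n_rural + [DENSELY_POPULATED] * (n - 2 * n_rural) + [URBAN] * n_rural)
    return pd.DataFrame({
        "area_id": [f"A{i:04d}" for i in range(n)],
        "older_share": np.clip(rng.normal(np.where(types == RURAL, 0.30, 0.18), 0.05), 0.01, 0.99),
        "high_edu_share": np.clip(rng.normal(0.3, 0.05, size=n), 0.01, 0.99),
        "median_income": rng.normal(280_000, 20_000, size=n),
        "has_station": rng.integers(0, 2, size=n),
        "area_type": types,
        "region": rng.choice(["region_a", "region_b"], size=n),
    })


class TestDisparityModels:
    def make_access(self, areas, rng, eta_fn, alpha=0.1):
        from ehc_access.accessibility import assign_quintiles

        mu = np.exp(eta_fn(areas))
        y = rng.poisson(rng.gamma(1.0 / alpha, mu * alpha)).astype(float)
        access = pd.DataFrame({"area_id": areas.area_id, "rt_min": y,
                               "tt_min": y, "tpt_min": y})
        for m in ("rt", "tt", "tpt"):
            access[f"quintile_{m}"] = assign_quintiles(access[f"{m}_min"].to_numpy())
        return access

    def test_quintile5_subset_size(self):
        rng = np.random.default_rng(9)
        areas = _areas_frame(2520, rng)
        access = self.make_access(areas, rng, lambda a: np.log(20) + 0.5 * (a.area_type == RURAL))
        res = fit_disparity_models(areas, access, ModelSpec("rt", subset="quintile5"))
        assert res.n == 504

    def test_interaction_absorbs_rural_main_effect(self):
        """With a true rural x older effect, the interaction model finds it
        and the rural dummy loses its (spurious) significance."""
        rng = np.random.default_rng(10)
        areas = _areas_frame(800, rng)

        def eta(a):
            rural = (a.area_type == RURAL).to_numpy(dtype=float)
            return np.log(15) + 4.0 * rural * a.older_share.to_numpy()

        access = self.make_access(areas, rng, eta)
        plain = fit_disparity_models(areas, access, ModelSpec("rt"))
        inter = fit_disparity_models(areas, access, ModelSpec("rt", with_interaction=True))
        assert plain.pvalue("rural") < 1e-10       # absorbs the interaction
        assert inter.pvalue("rural_x_older") < 1e-6
        # true rural main effect is zero: no longer significant at the 1%
        # level once the interaction term carries the signal
        assert inter.pvalue("rural") > 0.01
        assert abs(inter.estimate("rural")) < 0.5 * plain.estimate("rural")
        assert inter.estimate("rural_x_older") > 0

    def test_interaction_leaves_other_signs_unchanged(self):
        rng = np.random.default_rng(11)
        areas = _areas_frame(800, rng)

        def eta(a):
            return (np.log(20) + 2.0 * a.older_share.to_numpy()
                    - 1.5 * a.high_edu_share.to_numpy()
                    - 0.3 * a.has_station.to_numpy())

        access = self.make_access(areas, rng, eta)
        plain = fit_disparity_models(areas, access, ModelSpec("rt"))
        inter = fit_disparity_models(areas, access, ModelSpec("rt", with_interaction=True))
        for term in ("older_share", "high_edu_share", "has_station"):
            assert np.sign(plain.estimate(term)) == np.sign(inter.estimate(term))

    def test_unknown_measure_rejected(self):
        rng = np.random.default_rng(12)
        areas = _areas_frame(100, rng)
        access = self.make_access(areas, rng, lambda a: np.log(10) * np.ones(len(a)))
        with pytest.raises(ValueError):
            fit_disparity_models(areas, access, ModelSpec("speed"))

    def test_design_reference_categories(self):
        rng = np.random.default_rng(13)
        areas = _areas_frame(100, rng)
        X = build_design(areas, with_interaction=True)
        assert "const" in X.columns
        assert "dense" in X.columns and "rural" in X.columns
        assert not any(c == "region[region_a]" for c in X.columns)  # reference region
        assert "region[region_b]" in X.columns
        assert "rural_x_older" in X.columns
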
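"""Conventional fits, the hierarchical estimator and its oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import diimlm as d
from diimlm import model
from diimlm.errors import ValidationError


def hier_spec(tables, reference, covariates=None, **kwargs):
    return model.HierarchicalSpec(
        foods=tables.grams,
        composition=tables.composition,
        effect_scores=reference.set_index("parameter")["effect_score"],
        covariates=covariates,
        **kwargs,
    )


class TestFitSimple:
    def test_noiseless_line(self):
        x = np.linspace(0, 5, 20)
        fit = d.fit_simple(2 * x, x)
        assert fit.params["dii"] == pytest.approx(2.0)
        assert fit.se["dii"] == pytest.approx(0.0, abs=1e-10)

    def test_hand_ols(self):
        fit = d.fit_simple([1.0, 1.0, 4.0], [0.0, 1.0, 2.0])
        assert fit.params["dii"] == pytest.approx(1.5)  # cov(x,y)/var(x) by hand

    def test_permutation_invariance(self, rng):
        x = rng.normal(size=40)
        y = 1 + 2 * x + rng.normal(size=40)
        perm = rng.permutation(40)
        a, b = d.fit_simple(y, x), d.fit_simple(y[perm], x[perm])
        assert a.params["dii"] == pytest.approx(b.params["dii"])
        assert a.se["dii"] == pytest.approx(b.se["dii"])

    def test_constant_dii_rejected(self):
        with pytest.raises(ValidationError):
            d.fit_simple([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestFitMultiple:
    def test_orthogonal_design_matches_simple(self):
        dii = np.array([1.0, -1.0] * 4)
        other = np.array([1.0, 1.0, -1.0, -1.0] * 2)  # ⟂ dii and intercept
        y = 3 + 2 * dii + 0.5 * other
        mfit = d.fit_multiple(y, dii=dii, covariates=pd.DataFrame({"c": other}))
        sfit = d.fit_simple(y, dii)
        assert mfit.params["dii"] == pytest.approx(sfit.params["dii"])

    def test_duplicate_food_column_dropped(self, rng):
        foods = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        foods["c"] = foods["a"]  # exact alias
        dii = rng.normal(size=50)
        y = rng.normal(size=50)
        fit = d.fit_multiple(y, dii=dii, foods=foods)
        assert fit.dropped_columns == ["food::c"]
        manual = d.fit_multiple(y, dii=dii, foods=foods[["a", "b"]])
        assert np.allclose(
            fit.params[manual.params.index], manual.params, atol=1e-10
        )

    def test_exactly_nested_nutrients_protect_dii(self, small_cohort, small_reference):
        """Nutrient intakes are exact linear maps of food grams; the rank
        filter keeps the DII column and drops the aliased food columns."""
        tables, _ = small_cohort
        score = d.compute_dii(tables.intakes, small_reference, quartiles=False)
        y = tables.outcomes["stress"].to_numpy(float)
        fit = d.fit_multiple(
            y,
            dii=score["dii_overall"],
            nutrients=tables.intakes,
            foods=tables.grams,
        )
        assert "dii" in fit.params.index
        # composition has 10 independent columns -> 10 food columns aliased
        assert len(fit.dropped_columns) == 10
        assert all(c.startswith("food::") for c in fit.dropped_columns)

    def test_saturated_design_rejected(self, rng):
        foods = pd.DataFrame(rng.normal(size=(10, 12)))
        with pytest.raises(ValidationError, match="hierarchical"):
            d.fit_multiple(rng.normal(size=10), dii=rng.normal(size=10), foods=foods)


@pytest.fixture(scope="module")
def fixed_tau_case():
    ref = d.generate_reference_table(3, seed=9)
    cfg = d.SimulationConfig(
        n_participants=50, n_foods=5, n_nutrients=3,
        outlier_energy_fraction=0.0, seed=21,
    )
    tables, truth = d.generate_cohort(cfg, ref)
    cov = tables.covariates[["asset", "social_activity", "gender"]]
    y = tables.outcomes["stress_continuous"].to_numpy()
    return tables, ref, cov, y


class TestHierarchicalOracles:
    def test_matches_dense_gls_oracle(self, fixed_tau_case):
        """For fixed variance components the Woodbury/Henderson solve must
        equal a brute-force dense GLS with V = σ²I + τ_f²FFᵀ + τ_n²(FZ)(FZ)ᵀ."""
        tables, ref, cov, y = fixed_tau_case
        tf, tn, s2 = 0.7, 0.3, 25.0
        spec = hier_spec(tables, ref, covariates=cov,
                         tau2_food=tf, tau2_nutrient=tn, sigma2=s2)
        fit = d.fit_hierarchical(spec, y)
        F, Z, w, X, x_sd, names = spec.build()
        V = s2 * np.eye(len(y)) + tf * F @ F.T + tn * (F @ Z) @ (F @ Z).T
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ Vi @ X)))
        assert np.abs(fit.params.to_numpy() - b).max() < 1e-8
        assert np.abs(fit.se.to_numpy() - se).max() < 1e-8
        r = y - X @ b
        delta = tf * F.T @ Vi @ r
        theta = tn * (F @ Z).T @ Vi @ r
        assert np.abs(fit.delta_hat.to_numpy() - delta).max() < 1e-8
        assert np.abs(fit.theta_hat.to_numpy() - theta).max() < 1e-8

    def test_zero_tau_collapses_to_composite_ols(self, fixed_tau_case):
        tables, ref, cov, y = fixed_tau_case
        spec = hier_spec(tables, ref, covariates=cov,
                         tau2_food=0.0, tau2_nutrient=0.0)
        fit = d.fit_hierarchical(spec, y)
        F, Z, w, X, _, _ = spec.build()
        ols = sm.OLS(y, X).fit()
        assert fit.gamma == pytest.approx(ols.params[-1], abs=1e-10)
        # beta ≡ Z·w·γ_raw exactly; residual effects vanish
        assert np.abs(
            fit.beta_std.to_numpy() - Z @ (w * fit.gamma_raw)
        ).max() < 1e-12
        assert np.abs(fit.delta_hat.to_numpy()).max() == 0.0

    def test_huge_tau_matches_unpenalized_regression(self):
        ref = d.generate_reference_table(3, seed=9)
        cfg = d.SimulationConfig(
            n_participants=200, n_foods=5, n_nutrients=3,
            outlier_energy_fraction=0.0, seed=22,
        )
        tables, _ = d.generate_cohort(cfg, ref)
        cov = tables.covariates[["asset", "social_activity", "gender"]]
        y = tables.outcomes["stress_continuous"].to_numpy()
        spec = hier_spec(tables, ref, covariates=cov,
                         tau2_food=1e8, tau2_nutrient=1e8, sigma2=64.0)
        fit = d.fit_hierarchical(spec, y)
        F, _, _, X, _, _ = spec.build()
        ols = sm.OLS(y, np.column_stack([X[:, :-1], F])).fit()
        assert np.abs(fit.beta_std.to_numpy() - ols.params[-5:]).max() < 1e-3

    def test_scale_equivariance_of_variance_components(self, fixed_tau_case):
        tables, ref, cov, y = fixed_tau_case
        spec = hier_spec(tables, ref, covariates=cov)
        tf1, tn1, s1 = d.estimate_tau2_eb(spec, y)
        tf3, tn3, s3 = d.estimate_tau2_eb(spec, 3.0 * y)
        assert tf3 == pytest.approx(9 * tf1, rel=1e-3, abs=1e-8)
        assert tn3 == pytest.approx(9 * tn1, rel=1e-3, abs=1e-8)
        assert s3 == pytest.approx(9 * s1, rel=1e-3)

    def test_participant_permutation_invariance(self, fixed_tau_case, rng):
        tables, ref, cov, y = fixed_tau_case
        perm = rng.permutation(len(y))
        spec_a = hier_spec(tables, ref, covariates=cov,
                           tau2_food=0.5, tau2_nutrient=0.5, sigma2=30.0)
        spec_b = model.HierarchicalSpec(
            foods=tables.grams.iloc[perm],
            composition=tables.composition,
            effect_scores=ref.set_index("parameter")["effect_score"],
            covariates=cov.iloc[perm],
            tau2_food=0.5, tau2_nutrient=0.5, sigma2=30.0,
        )
        fa = d.fit_hierarchical(spec_a, y)
        fb = d.fit_hierarchical(spec_b, y[perm])
        assert fa.gamma == pytest.approx(fb.gamma, abs=1e-10)
        assert np.allclose(fa.beta_std, fb.beta_std, atol=1e-10)

    def test_food_label_invariance(self, fixed_tau_case, rng):
        """Reordering foods with a consistently permuted bridge changes
        nothing but the labels."""
        tables, ref, cov, y = fixed_tau_case
        food_perm = rng.permutation(tables.grams.columns)
        spec_a = hier_spec(tables, ref, covariates=cov,
                           tau2_food=0.5, tau2_nutrient=0.5, sigma2=30.0)
        spec_b = model.HierarchicalSpec(
            foods=tables.grams[food_perm],
            composition=tables.composition.loc[food_perm],
            effect_scores=ref.set_index("parameter")["effect_score"],
            covariates=cov,
            tau2_food=0.5, tau2_nutrient=0.5, sigma2=30.0,
        )
        fa = d.fit_hierarchical(spec_a, y)
        fb = d.fit_hierarchical(spec_b, y)
        assert fa.gamma == pytest.approx(fb.gamma, abs=1e-10)
        assert np.allclose(
            fa.beta_std[food_perm].to_numpy(), fb.beta_std.to_numpy(), atol=1e-10
        )

    def test_shrinkage_interpolates_between_prior_and_ols(self, rng):
        """As τ² grows 0 → ∞ the food coefficients move monotonically from
        the nutrient-composition prediction toward the unpenalized OLS fit."""
        n = 60
        foods = pd.DataFrame(rng.normal(size=(n, 2)), columns=["f1", "f2"])
        comp = pd.DataFrame({"nut": [1.0, 3.0]}, index=["f1", "f2"])
        w = pd.Series({"nut": 0.5})
        y = 1.0 + foods["f1"] * 0.8 - foods["f2"] * 0.3 + rng.normal(size=n)
        y = y.to_numpy()

        def beta_at(tau):
            spec = model.HierarchicalSpec(
                foods=foods, composition=comp, effect_scores=w,
                tau2_food=tau, tau2_nutrient=tau, sigma2=1.0,
            )
            return d.fit_hierarchical(spec, y).beta_std.to_numpy()

        Fs, _, _ = model.standardize_columns(foods)
        ols = sm.OLS(y, sm.add_constant(Fs.to_numpy())).fit().params[1:]
        b0 = beta_at(0.0)
        dist_to_ols = [np.linalg.norm(beta_at(t) - ols)
                       for t in (0.0, 0.1, 1.0, 10.0, 1e4)]
        dist_to_prior = [np.linalg.norm(beta_at(t) - b0)
                         for t in (0.0, 0.1, 1.0, 10.0, 1e4)]
        assert all(np.diff(dist_to_ols) < 1e-9)
        assert all(np.diff(dist_to_prior) > -1e-9)

    def test_null_variance_components_shrink_to_zero(self):
        """With δ = θ = 0 in truth, REML τ² estimates sit near zero."""
        hits = 0
        for r in range(5):
            cfg = d.SimulationConfig(
                n_participants=2000, n_foods=30, n_nutrients=10,
                food_residual_sd=0.0, nutrient_residual_sd=0.0,
                outlier_energy_fraction=0.0, seed=4000 + r,
            )
            ref = d.generate_reference_table(10, seed=200 + r)
            tables, _ = d.generate_cohort(cfg, ref)
            spec = hier_spec(tables, ref, shared_tau2=False)
            tf, tn, _ = d.estimate_tau2_eb(
                spec, tables.outcomes["stress_continuous"].to_numpy()
            )
            hits += (tf < 0.05) and (tn < 0.05)
        assert hits >= 4


class TestBaselineAssociations:
    def test_identical_groups_t_zero(self):
        outcomes = pd.DataFrame({"stress": [5.0] * 10})
        cov = pd.DataFrame({"gender": [0] * 5 + [1] * 5})
        rep = d.baseline_associations(outcomes, cov, types={"gender": "binary"})
        row = rep.iloc[0]
        assert row["statistic"] == 0.0 and row["p_value"] == 1.0

    def test_two_sample_t_closed_form(self):
        outcomes = pd.DataFrame({"stress": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        cov = pd.DataFrame({"g": [0, 0, 0, 1, 1, 1]})
        rep = d.baseline_associations(outcomes, cov, types={"g": "binary"})
        row = rep.iloc[0]
        # pooled variance 1, t = -3/sqrt(2/3), df = 4 (textbook arithmetic)
        assert row["statistic"] == pytest.approx(-3.674234614, abs=1e-6)
        assert row["p_value"] == pytest.approx(0.021312, abs=1e-4)

    def test_anova_null_p_uniform(self, rng):
        """Under equal group means the ANOVA p-values are uniform."""
        from scipy import stats

        pvals = []
        for _ in range(300):
            y = rng.normal(size=30)
            g = np.repeat([0, 1, 2], 10)
            rep = d.baseline_associations(
                pd.DataFrame({"y": y}), pd.DataFrame({"g": g}),
                types={"g": "categorical"},
            )
            pvals.append(rep.iloc[0]["p_value"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_group_undefined_not_fatal(self):
        outcomes = pd.DataFrame({"stress": [1.0, 2.0, 3.0, 4.0]})
        cov = pd.DataFrame({"g": [0, 0, 0, 1]})  # one group has n=1
        rep = d.baseline_associations(outcomes, cov, types={"g": "binary"})
        assert np.isnan(rep.iloc[0]["p_value"])
        assert "undefined" in rep.iloc[0]["detail"]

    def test_continuous_slope_reported(self, rng):
        x = rng.normal(size=200)
        y = 2.0 + 0.5 * x + rng.normal(size=200)
        rep = d.baseline_associations(
            pd.DataFrame({"stress": y}), pd.DataFrame({"asset": x}),
            types={"asset": "continuous"},
        )
        assert "slope" in rep.iloc[0]["detail"]
        assert rep.iloc[0]["p_value"] < 0.001


class TestCompareModels:
    def test_three_rows_and_flag(self, small_cohort, small_reference):
        tables, _ = small_cohort
        score = d.compute_dii(tables.intakes, small_reference, quartiles=False)
        y = tables.outcomes["stress"].to_numpy(float)
        sfit = d.fit_simple(y, score["dii_overall"], outcome_name="stress")
        mfit = d.fit_multiple(
            y, dii=score["dii_overall"], covariates=tables.covariates,
            nutrients=tables.intakes, foods=tables.grams, outcome_name="stress",
        )
        spec = model.HierarchicalSpec(
            foods=tables.grams, composition=tables.composition,
            effect_scores=small_reference.set_index("parameter")["effect_score"],
            covariates=tables.covariates, outcome_name="stress",
        )
        hfit = d.fit_hierarchical(spec, y)
        rep = d.compare_models([sfit, mfit, hfit])
        assert len(rep) == 3
        assert rep["hierarchical_narrower"].dtype == bool

    def test_mismatched_fits_rejected(self, rng):
        x = rng.normal(size=30)
        a = d.fit_simple(2 * x + rng.normal(size=30), x, outcome_name="stress")
        b = d.fit_simple(2 * x + rng.normal(size=30), x, outcome_name="anxiety")
        with pytest.raises(ValidationError):
            d.compare_models([a, b])
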
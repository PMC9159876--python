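import numpy as np
import pandas as pd
import pytest

from painmap import sfmpq2
from painmap.glmm import (
    MODEL_PREDICTORS,
    HierarchicalModel,
    MCMCSettings,
    ModelSpec,
    build_model_specs,
    compute_rhat,
    fit_all_models,
    fit_model,
    gibbs_sample,
    standardize,
    summarize_posterior,
)

from conftest import reduced_settings


def fixed_dataset(n=20, seed=7, sigma=1.0):
    """A frozen fixed-effects regression dataset for oracle comparisons."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    beta = np.array([0.5, 1.0, -1.0])
    y = X @ beta + sigma * rng.standard_normal(n)
    return X, y


def nig_flat_posterior(X, y):
    """Closed-form posterior under the flat-prior normal-inverse-gamma limit."""
    n, p = X.shape
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(np.sum((y - X @ bhat) ** 2))
    a_n = 1e-3 + (n - p) / 2.0
    b_n = 1e-3 + ssr / 2.0
    e_sigma2 = b_n / (a_n - 1.0)
    cov = e_sigma2 * np.linalg.inv(X.T @ X)
    return bhat, np.diag(cov)


class TestModelSpecs:
    def test_ten_specs_from_five_predictor_sets(self):
        specs = build_model_specs()
        assert len(specs) == 10
        assert {s.dependent for s in specs} == {"extension_activity", "distance_cm"}
        assert sum(s.dependent == "distance_cm" for s in specs) == 5

    def test_neuropathic_model_includes_light_touch(self):
        spec = next(
            s for s in build_model_specs()
            if s.model_name == "neuropathic" and s.dependent == "extension_activity"
        )
        assert len(spec.predictors) == 6
        assert "light_touch" in spec.predictors

    def test_affective_model_has_four_predictors(self):
        spec = next(s for s in build_model_specs() if s.model_name == "affective")
        assert spec.predictors == sfmpq2.AFFECTIVE_ITEMS

    def test_total_predictor_rows_match_report_layout(self):
        per_dependent = sum(
            len(s.predictors)
            for s in build_model_specs()
            if s.dependent == "distance_cm"
        )
        assert per_dependent == 26


class TestStandardize:
    def test_closed_form(self):
        z, mean, sd = standardize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotent(self):
        z, *_ = standardize(np.random.default_rng(0).normal(3, 2, 50))
        z2, *_ = standardize(z)
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(np.full(10, 4.2))


class TestGibbsSampler:
    def test_deterministic_given_seed(self):
        X, y = fixed_dataset()
        model = HierarchicalModel(y=y, X=X, coef_names=["b0", "b1", "b2"])
        settings = MCMCSettings(n_iterations=200, n_burn_in=100, n_chains=2, seed=5)
        a = gibbs_sample(model, settings)
        b = gibbs_sample(model, settings)
        for name in a:
            np.testing.assert_array_equal(a[name], b[name])

    def test_fixed_effects_posterior_matches_conjugate_oracle(self):
        X, y = fixed_dataset()
        mean_oracle, var_oracle = nig_flat_posterior(X, y)
        model = HierarchicalModel(y=y, X=X, coef_names=["b0", "b1", "b2"])
        chains = gibbs_sample(
            model, MCMCSettings(n_iterations=4000, n_burn_in=1000, n_chains=8, seed=1)
        )
        for j, name in enumerate(["b0", "b1", "b2"]):
            draws = chains[name]
            chain_means = draws.mean(axis=1)
            mcse = chain_means.std(ddof=1) / np.sqrt(len(chain_means))
            assert abs(draws.mean() - mean_oracle[j]) < 3 * mcse
            chain_vars = draws.var(axis=1, ddof=1)
            mcse_v = chain_vars.std(ddof=1) / np.sqrt(len(chain_vars))
            assert abs(draws.var(ddof=1) - var_oracle[j]) < 3 * mcse_v

    def test_noiseless_response_concentrates_on_unit_slope(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(60)
        y = x + 1e-4 * rng.standard_normal(60)
        model = HierarchicalModel(
            y=y, X=np.column_stack([np.ones(60), x]), coef_names=["b0", "b1"]
        )
        chains = gibbs_sample(
            model, MCMCSettings(n_iterations=2000, n_burn_in=500, n_chains=2, seed=0)
        )
        assert abs(chains["b1"].mean() - 1.0) < 0.05

    def test_rank_deficient_design_names_columns(self):
        x = np.random.default_rng(0).standard_normal(30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            HierarchicalModel(y=x, X=X, coef_names=["b0", "b1", "b1_copy"])

    def test_non_finite_response_rejected(self):
        X, y = fixed_dataset()
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            HierarchicalModel(y=y, X=X, coef_names=["b0", "b1", "b2"])

    def test_permutation_invariant_sufficient_statistics(self):
        rng = np.random.default_rng(8)
        n, G = 69, 23
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = rng.standard_normal(n)
        g = np.repeat(np.arange(G), 3)
        perm = rng.permutation(n)
        Xp, yp, gp = X[perm], y[perm], g[perm]
        np.testing.assert_allclose(X.T @ X, Xp.T @ Xp, atol=1e-10)
        np.testing.assert_allclose(X.T @ y, Xp.T @ yp, atol=1e-10)
        for j in range(X.shape[1]):
            np.testing.assert_allclose(
                np.bincount(g, weights=X[:, j], minlength=G),
                np.bincount(gp, weights=Xp[:, j], minlength=G),
                atol=1e-10,
            )
        np.testing.assert_allclose(
            np.bincount(g, weights=y, minlength=G),
            np.bincount(gp, weights=yp, minlength=G),
            atol=1e-10,
        )


class TestRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 20_000))
        assert compute_rhat(chains) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert compute_rhat(chains) > 5.0

    def test_matches_independent_formula_evaluation(self):
        rng = np.random.default_rng(42)
        chains = rng.normal(0, 1, (3, 200)) + np.array([[0.0], [0.1], [-0.05]])

        # independent spelled-out evaluation of split-Rhat
        halves = []
        for c in chains:
            half = len(c) // 2
            halves.append(c[:half])
            halves.append(c[half : 2 * half])
        halves = np.array(halves)
        m, n = halves.shape
        W = np.mean([np.var(h, ddof=1) for h in halves])
        B = n * np.var([h.mean() for h in halves], ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)

        assert compute_rhat(chains) == pytest.approx(expected, abs=1e-6)

    def test_degenerate_chains_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_rhat(np.ones((2, 100)))

    def test_too_few_draws_error(self):
        with pytest.raises(ValueError, match="4"):
            compute_rhat(np.random.default_rng(0).normal(size=(2, 3)))


class TestPosteriorSummary:
    def test_constant_draws_summarized_with_nan_rhat(self):
        s = summarize_posterior({"c": np.full((2, 100), 3.5)}).iloc[0]
        assert s["estimate"] == 3.5
        assert (s["ci_low"], s["ci_high"]) == (3.5, 3.5)
        assert np.isnan(s["rhat"])
        assert s["credibly_nonzero"]

    def test_linear_interpolation_quantiles(self):
        draws = np.arange(1, 1001, dtype=float).reshape(2, 500)
        s = summarize_posterior({"x": draws}).iloc[0]
        assert s["ci_low"] == pytest.approx(25.975)
        assert s["ci_high"] == pytest.approx(975.025)

    def test_sign_flag_matches_interval(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(0.53, 0.1, (2, 1000))  # CI well above 0
        near = rng.normal(0.0, 1.0, (2, 1000))
        s = summarize_posterior({"pos": pos, "near": near}).set_index("parameter")
        assert s.loc["pos", "credibly_nonzero"]
        assert not s.loc["near", "credibly_nonzero"]


class TestFitAllModels:
    @staticmethod
    def synthetic_tables(n_patients=8, seed=0):
        rng = np.random.default_rng(seed)
        patients = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n_patients)]})
        for name in sfmpq2.ITEM_NAMES:
            patients[name] = rng.integers(0, 6, n_patients)
        for sub, members in sfmpq2.SUBCLASSES.items():
            patients[sub] = patients[list(members)].sum(axis=1)
        patients["nrs"] = rng.integers(1, 10, n_patients)
        rows = []
        for pid in patients["patient_id"]:
            for t in (1, 2, 3):
                rows.append(
                    {
                        "patient_id": pid,
                        "trial_id": t,
                        "extension_activity": rng.normal(1.0, 0.1),
                        "distance_cm": abs(rng.normal(10, 3)),
                    }
                )
        return pd.DataFrame(rows), patients

    def test_report_tables_have_26_predictor_rows_each(self):
        outcomes, patients = self.synthetic_tables()
        report = fit_all_models(outcomes, patients, reduced_settings(1))
        assert set(report.tables) == {"extension_activity", "distance_cm"}
        for table in report.tables.values():
            assert len(table) == 26
            assert list(table.columns) == [
                "Model", "Variables", "Estimate", "Lower CI", "Upper CI", "Rhat",
            ]
        assert len(report.summary) == 52

    def test_constant_predictor_reported_not_fatal(self):
        outcomes, patients = self.synthetic_tables()
        patients["splitting"] = 0  # rare item, constant across cohort
        patients["intermittent_pain"] = patients[
            list(sfmpq2.INTERMITTENT_ITEMS)
        ].sum(axis=1)
        with pytest.warns(RuntimeWarning, match="splitting"):
            report = fit_all_models(outcomes, patients, reduced_settings(2))
        row = report.summary.query(
            "parameter == 'splitting' and dependent == 'distance_cm'"
        ).iloc[0]
        assert np.isnan(row["estimate"])
        assert not row["credibly_nonzero"]
        assert len(report.tables["distance_cm"]) == 26

    def test_unknown_patient_key_rejected(self):
        outcomes, patients = self.synthetic_tables()
        outcomes.loc[0, "patient_id"] = "P999"
        with pytest.raises(ValueError, match="P999"):
            fit_all_models(outcomes, patients, reduced_settings(3))

    def test_missing_join_column_rejected(self):
        outcomes, patients = self.synthetic_tables()
        with pytest.raises(ValueError, match="patient_id"):
            fit_all_models(outcomes.drop(columns="patient_id"), patients,
                           reduced_settings(4))
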
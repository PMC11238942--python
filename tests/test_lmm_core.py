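"""Core mixed-model machinery: coefficient tables, design construction,
REML fitting, BLUPs and grouped ridge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mmsetraj as mt
from mmsetraj.lmm_core import (
    TIME_TERMS,
    DesignBundle,
    _marginal_precision_products,
    build_design,
    default_ridge_groups,
    evaluate_table,
    fit_grouped_ridge,
    fit_reml,
)
from mmsetraj.synthetic_cohort import CovariateSpec

from conftest import true_structure_terms


class TestCoefficientTable:
    def test_round_trip_serialization(self, mci_table, tmp_path):
        path = tmp_path / "coef.json"
        mci_table.to_json(path)
        back = mt.CoefficientTable.from_json(path)
        assert back.entries == mci_table.entries
        assert back.se == mci_table.se
        assert back.time_center == mci_table.time_center
        assert back.bounds == mci_table.bounds

    def test_interaction_without_main_rejected(self):
        with pytest.raises(ValueError, match="without main effect"):
            mt.CoefficientTable(
                group="MCI",
                entries={"intercept": 1.0, "t1": -1.0, "abeta42:t": 0.1},
            )

    def test_published_tables_have_expected_structure(self, mci_table, dem_table):
        assert len(mci_table.entries) == 13
        assert len(dem_table.entries) == 14
        for table in (mci_table, dem_table):
            assert table.time_center == 2.3
            assert table.bounds == (0.0, 30.0)
            assert set(TIME_TERMS) <= set(table.entries)
            assert set(table.se) == set(table.entries)

    def test_required_covariates_resolve_transforms(self, mci_table):
        req = set(mci_table.required_covariates())
        assert "log_ptau" in req
        assert {"age", "sex", "mmse_bl", "abeta42"} <= req


class TestEvaluateTable:
    def test_value_at_centering_point_is_constant_part(self, dem_table, prognosis_dem_patient):
        """At t = 2.3 the polynomial and every interaction vanish, so the
        prediction is exactly the covariate-weighted constant part -- 15.13
        for the worked mild-dementia profile."""
        cov = prognosis_dem_patient.resolved_for(dem_table)
        val = evaluate_table(dem_table, cov, [2.3])[0]
        e = dem_table.entries
        expected = (
            e["intercept"] + e["age"] * 66 + e["sex"] * 0 + e["mmse_bl"] * 20
            + e["apoe4"] * 2 + e["log_ptau"] * 3.498 + e["abeta42"] * 625
        )
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(15.131, abs=0.001)

    def test_log_transform_resolved_from_raw_value(self, mci_table):
        cov_raw = {"age": 66, "sex": 1, "mmse_bl": 27, "ptau": np.exp(3.415), "abeta42": 796.22}
        cov_log = {"age": 66, "sex": 1, "mmse_bl": 27, "log_ptau": 3.415, "abeta42": 796.22}
        t = np.linspace(0, 5, 11)
        np.testing.assert_allclose(
            evaluate_table(mci_table, cov_raw, t), evaluate_table(mci_table, cov_log, t)
        )

    def test_missing_covariate_raises(self, mci_table):
        with pytest.raises(KeyError, match="abeta42"):
            evaluate_table(mci_table, {"age": 66, "sex": 1, "mmse_bl": 27, "log_ptau": 3.4}, [0.0])

    @given(
        beta_x=st.floats(-2, 2),
        beta_xt=st.floats(-1, 1),
        x=st.floats(-5, 5),
        t=st.floats(0, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_covariate_and_centered_time(self, beta_x, beta_xt, x, t):
        table = mt.CoefficientTable(
            group="MCI",
            entries={"intercept": 10.0, "t1": -1.0, "x": beta_x, "x:t": beta_xt},
            time_center=2.3,
        )
        val = evaluate_table(table, {"x": x}, [t])[0]
        expected = 10.0 - 1.0 * (t - 2.3) + beta_x * x + beta_xt * x * (t - 2.3)
        assert val == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestBuildDesign:
    def test_columns_and_interaction_algebra(self, small_complete_cohort):
        terms = true_structure_terms()
        bundle = build_design(small_complete_cohort, terms, 2.3)
        expected_cols = {"intercept", "t1", "t2", "t3", "age", "sex", "mmse_bl",
                         "log_ptau", "abeta42", "age:t", "sex:t", "log_ptau:t", "abeta42:t"}
        assert set(bundle.X.columns) == expected_cols
        np.testing.assert_allclose(bundle.X["t2"], bundle.X["t1"] ** 2)
        np.testing.assert_allclose(bundle.X["age:t"], bundle.X["age"] * bundle.X["t1"])
        assert bundle.n_obs == len(bundle.y) == bundle.X.shape[0]
        # random design is (1, raw time)
        np.testing.assert_allclose(bundle.exog_re[:, 0], 1.0)
        np.testing.assert_allclose(bundle.exog_re[:, 1], bundle.X["t1"] + 2.3)

    def test_missing_covariate_values_rejected(self, small_missing_cohort):
        with pytest.raises(ValueError, match="impute"):
            build_design(small_missing_cohort, true_structure_terms(), 2.3)

    def test_collinear_design_names_columns(self, small_complete_cohort):
        terms = (*true_structure_terms(), mt.ModelTerm("age2", role="constant"))
        cohort = small_complete_cohort.copy()
        cohort.baseline["age2"] = 2.0 * cohort.baseline["age"]
        bundle = build_design(cohort, terms, 2.3)
        with pytest.raises(ValueError, match="age2|age"):
            fit_reml(bundle)


@pytest.fixture(scope="module")
def structural_fit(small_complete_cohort):
    bundle = build_design(small_complete_cohort, true_structure_terms(), 2.3)
    return bundle, fit_reml(bundle, raise_on_nonconvergence=False)


class TestFitReml:
    def test_fixed_effects_are_gls_at_fitted_variance_components(self, structural_fit):
        """Independent check: the reported fixed effects must solve the GLS
        normal equations at the reported variance components, computed here
        directly from per-subject marginal covariance matrices."""
        bundle, fit = structural_fit
        X = bundle.X.to_numpy()
        p = X.shape[1]
        A, b = np.zeros((p, p)), np.zeros(p)
        for sid in pd.unique(bundle.groups):
            ii = bundle.groups == sid
            Zi = bundle.exog_re[ii]
            Vi = Zi @ fit.re_cov @ Zi.T + fit.resid_var * np.eye(ii.sum())
            Vinv = np.linalg.inv(Vi)
            A += X[ii].T @ Vinv @ X[ii]
            b += X[ii].T @ Vinv @ bundle.y[ii]
        beta_gls = np.linalg.solve(A, b)
        beta_fit = np.array([fit.coefficients.entries[n] for n in bundle.X.columns])
        np.testing.assert_allclose(beta_fit, beta_gls, rtol=1e-5, atol=1e-6)
        # and the reported SEs match the GLS information matrix
        se_gls = np.sqrt(np.diag(np.linalg.inv(A)))
        se_fit = np.array([fit.coefficients.se[n] for n in bundle.X.columns])
        np.testing.assert_allclose(se_fit, se_gls, rtol=1e-2, atol=1e-6)

    def test_parameter_recovery_within_three_se(self, mci_table):
        cfg = mt.CohortConfig(
            n_subjects=600, group="MCI", seed=17, round_outcomes=False,
            dropout_hazard_per_year=0.0, visit_jitter=0.0,
        )
        cohort = mt.generate_cohort(cfg, with_missingness=False)
        bundle = build_design(cohort, true_structure_terms(), 2.3)
        fit = fit_reml(bundle, raise_on_nonconvergence=False)
        misses = []
        for name, truth in mci_table.entries.items():
            est, se = fit.coefficients.entries[name], fit.coefficients.se[name]
            if abs(est - truth) > 3 * se:
                misses.append(name)
        assert len(misses) <= 1, misses  # allow a single 3-sigma excursion
        # variance components near the generator's values
        assert fit.re_cov[0, 0] == pytest.approx(4.0, rel=0.35)
        assert fit.re_cov[1, 1] == pytest.approx(1.0, rel=0.35)
        assert fit.resid_var == pytest.approx(1.5**2, rel=0.35)

    def test_refit_is_deterministic(self, structural_fit, small_complete_cohort):
        bundle, fit = structural_fit
        again = fit_reml(build_design(small_complete_cohort, true_structure_terms(), 2.3),
                         raise_on_nonconvergence=False)
        for n, v in fit.coefficients.entries.items():
            assert again.coefficients.entries[n] == pytest.approx(v, abs=1e-8)

    def test_row_order_invariance(self, small_complete_cohort, structural_fit):
        _, fit = structural_fit
        shuffled = small_complete_cohort.copy()
        shuffled.long = shuffled.long.sample(frac=1.0, random_state=3).reset_index(drop=True)
        refit = fit_reml(build_design(shuffled, true_structure_terms(), 2.3),
                         raise_on_nonconvergence=False)
        for n, v in fit.coefficients.entries.items():
            assert refit.coefficients.entries[n] == pytest.approx(v, abs=1e-5)

    def test_too_few_subjects_rejected(self, small_complete_cohort):
        solo = small_complete_cohort.subset(small_complete_cohort.baseline.index[:1])
        with pytest.raises(ValueError, match="2 subjects"):
            fit_reml(build_design(solo, true_structure_terms(), 2.3))


def test_null_covariate_p_values_are_uniform():
    """Wald p-values for a covariate with no true effect are uniform: across
    replications the rejection rate at 0.05 sits in its binomial band and a
    KS test does not reject uniformity."""
    from scipy import stats

    table = mt.CoefficientTable(group="MCI", entries={"intercept": 20.0, "t1": -0.5})
    reps, pvals = 150, []
    for r in range(reps):
        cfg = mt.CohortConfig(
            n_subjects=60, group="MCI", true_coefficients=table,
            covariate_params={"age": CovariateSpec("normal", 0.0, 1.0)},
            re_sd_intercept=1.0, re_sd_slope=0.3, re_corr=0.0, resid_sd=1.5,
            dropout_hazard_per_year=0.0, visit_jitter=0.0, round_outcomes=False,
            max_followup_years=3.0, seed=1000 + r,
        )
        cohort = mt.generate_cohort(cfg, with_missingness=False)
        bundle = build_design(cohort, (mt.ModelTerm("age", role="constant"),), 2.3)
        fit = fit_reml(bundle, raise_on_nonconvergence=False)
        pvals.append(fit.coef_p["age"])
    pvals = np.asarray(pvals)
    pvals = pvals[np.isfinite(pvals)]  # rare boundary fits yield no Wald p
    assert len(pvals) > 0.9 * reps
    rate = (pvals < 0.05).mean()
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps) + 0.01
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestBlups:
    def test_blups_average_near_zero_and_shrink(self, structural_fit):
        bundle, fit = structural_fit
        blups = mt.estimate_blups(fit)
        assert set(blups.columns) == {"b0", "b1"}
        assert abs(blups["b0"].mean()) < 0.3
        assert abs(blups["b1"].mean()) < 0.2
        # shrinkage: spread of estimated effects below the fitted RE spread
        assert blups["b0"].var() <= fit.re_cov[0, 0] * 1.05
        assert blups["b1"].var() <= fit.re_cov[1, 1] * 1.05

    def test_blups_improve_within_sample_fit(self, structural_fit):
        bundle, fit = structural_fit
        blups = mt.estimate_blups(fit)
        X = bundle.X.to_numpy()
        beta = np.array([fit.coefficients.entries[n] for n in bundle.X.columns])
        fixed = X @ beta
        b0 = blups["b0"].reindex(bundle.groups).to_numpy()
        b1 = blups["b1"].reindex(bundle.groups).to_numpy()
        with_re = fixed + b0 + b1 * bundle.time
        sse_fixed = np.sum((bundle.y - fixed) ** 2)
        sse_re = np.sum((bundle.y - with_re) ** 2)
        assert sse_re < sse_fixed

    def test_unknown_subject_rejected(self, structural_fit):
        _, fit = structural_fit
        with pytest.raises(KeyError, match="nobody"):
            mt.estimate_blups(fit, ["nobody"])


class TestGroupedRidge:
    def test_default_groups_partition_columns(self, structural_fit):
        bundle, _ = structural_fit
        groups = default_ridge_groups(bundle.X.columns)
        flat = [n for names in groups.groups.values() for n in names]
        assert sorted(flat) == sorted(n for n in bundle.X.columns if n != "intercept")
        assert groups.group_of("t2") == "time_curve"
        assert groups.group_of("mmse_bl") == "baseline_outcome"
        assert groups.group_of("abeta42:t") == "time_varying"
        assert groups.group_of("age") == "constant"
        assert groups.group_of("intercept") is None

    def test_duplicate_assignment_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            mt.RidgeGroups(groups={"a": ["x"], "b": ["x"]})

    def test_zero_penalty_reproduces_reml_fixed_effects(self, structural_fit):
        bundle, fit = structural_fit
        groups = default_ridge_groups(bundle.X.columns)
        ridge = fit_grouped_ridge(
            bundle, groups, {g: 0.0 for g in groups.groups}, base_fit=fit
        )
        for n, v in fit.coefficients.entries.items():
            assert ridge.coefficients.entries[n] == pytest.approx(v, abs=1e-6)

    def test_huge_penalty_annihilates_penalized_groups(self, structural_fit):
        bundle, fit = structural_fit
        groups = default_ridge_groups(bundle.X.columns)
        ridge = fit_grouped_ridge(
            bundle, groups, {g: 1e12 for g in groups.groups}, base_fit=fit
        )
        for n, v in ridge.coefficients.entries.items():
            if n != "intercept":
                assert abs(v) < 1e-4, (n, v)
        # intercept absorbs the (GLS-weighted) outcome level
        assert 0 < ridge.coefficients.entries["intercept"] < 30

    def test_penalty_monotonically_shrinks_standardized_norm(self, structural_fit):
        bundle, fit = structural_fit
        groups = default_ridge_groups(bundle.X.columns)
        sds = bundle.X.std(ddof=0)
        norms = []
        for lam in (0.0, 10.0, 1e3, 1e6):
            ridge = fit_grouped_ridge(bundle, groups, {g: lam for g in groups.groups},
                                      base_fit=fit)
            norms.append(sum((ridge.coefficients.entries[n] * sds[n]) ** 2
                             for n in bundle.X.columns if n != "intercept"))
        assert norms == sorted(norms, reverse=True)

    def test_tuned_penalties_are_deterministic(self, small_complete_cohort, structural_fit):
        bundle, fit = structural_fit
        a = fit_grouped_ridge(bundle, seed=4, base_fit=fit)
        b = fit_grouped_ridge(bundle, seed=4, base_fit=fit)
        assert a.method == b.method
        for n, v in a.coefficients.entries.items():
            assert b.coefficients.entries[n] == pytest.approx(v, abs=1e-10)
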
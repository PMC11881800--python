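"""Cohort statistics: PCA, mediation path models, BH correction, group tests,
reading regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsconn.cohort import (
    bh_adjust,
    compare_groups,
    fit_mediation,
    fit_reading_regression,
    run_mediation_battery,
    run_pca,
)
from nirsconn.synthetic import CohortSpec, generate_cohort


class TestRunPca:
    def test_independent_variables_give_near_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            rng.standard_normal((3000, 10)), columns=[f"v{i}" for i in range(10)]
        )
        res = run_pca(data, variables=list(data.columns), rotation=None)
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.2)

    def test_correlated_pair_gives_leading_eigenvalue_two(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(4000)
        data = pd.DataFrame(
            {
                "a": base,
                "b": base + 1e-3 * rng.standard_normal(4000),
                **{f"v{i}": rng.standard_normal(4000) for i in range(4)},
            }
        )
        res = run_pca(data, variables=list(data.columns), rotation=None)
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=0.05)

    def test_synthetic_cohort_recovers_three_blocks(self, default_cohort):
        res = run_pca(default_cohort["clinical"])
        assert res.n_retained == 3
        # development block loads together on one component
        pat = res.loadings.abs()
        dev_comp = pat.loc["age_at_testing"].idxmax()
        assert pat.loc["hearing_age", dev_comp] > 0.5
        primary_comp = pat.loc["age_first_ci"].idxmax()
        assert pat.loc["dur_deaf_first_ci", primary_comp] > 0.5
        assert dev_comp != primary_comp

    def test_scores_uncorrelated_before_rotation(self, default_cohort):
        res = run_pca(default_cohort["clinical"])
        gram = np.corrcoef(res.scores.to_numpy().T)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_variance_explained_nonincreasing(self, default_cohort):
        res = run_pca(default_cohort["clinical"])
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_constant_variable_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {
                "c": np.ones(200),
                **{f"v{i}": rng.standard_normal(200) for i in range(4)},
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            res = run_pca(data, variables=list(data.columns), rotation=None)
        assert "c" in res.dropped_variables

    def test_rank_deficient_correlation_rejected(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(300)
        data = pd.DataFrame(
            {
                "a": base,
                "b": 2.0 * base,  # exact collinearity
                **{f"v{i}": rng.standard_normal(300) for i in range(3)},
            }
        )
        with pytest.raises(np.linalg.LinAlgError):
            run_pca(data, variables=list(data.columns))


class TestFitMediation:
    def _simulate(self, a, b, cprime, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        m = a * x + np.sqrt(max(1 - a**2, 0.05)) * rng.standard_normal(n)
        y = b * m + cprime * x + rng.standard_normal(n)
        return x, m, y

    def test_total_equals_direct_plus_indirect(self):
        x, m, y = self._simulate(-0.5, 0.4, -0.15, 200, seed=0)
        res = fit_mediation(x, m, y, n_boot=50, seed=0)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-6)

    def test_matches_statsmodels_ols_oracle(self):
        import statsmodels.api as sm

        x, m, y = self._simulate(0.3, 0.5, 0.2, 300, seed=1)
        res = fit_mediation(x, m, y, n_boot=0, seed=1)
        a_fit = sm.OLS(m, sm.add_constant(x)).fit()
        y_fit = sm.OLS(y, sm.add_constant(np.column_stack([m, x]))).fit()
        assert res.a == pytest.approx(a_fit.params[1], abs=1e-10)
        assert res.b == pytest.approx(y_fit.params[1], abs=1e-10)
        assert res.direct == pytest.approx(y_fit.params[2], abs=1e-10)

    def test_null_b_path_ci_covers_zero(self):
        covered = 0
        n_sims = 40
        for seed in range(n_sims):
            x, m, y = self._simulate(-0.5, 0.0, 0.1, 200, seed=seed)
            res = fit_mediation(x, m, y, n_boot=300, seed=seed)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered >= 0.85 * n_sims

    def test_recovers_planted_indirect_effect(self):
        estimates = [
            fit_mediation(*self._simulate(-0.5, 0.4, -0.15, 500, seed=s), n_boot=0).indirect
            for s in range(50)
        ]
        assert np.mean(estimates) == pytest.approx(-0.2, abs=0.02)

    def test_zero_variance_mediator_rejected(self):
        x = np.random.default_rng(0).standard_normal(50)
        with pytest.raises(ValueError, match="variance"):
            fit_mediation(x, np.ones(50), x, n_boot=10)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="10"):
            fit_mediation(np.arange(5.0), np.arange(5.0) + 1, np.arange(5.0), n_boot=10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        # p(i) * m / i with cumulative minimum from the largest rank
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        np.testing.assert_allclose(bh_adjust(p), [0.05] * 5, atol=1e-12)

    def test_all_ones_capped(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_input_order_preserved(self):
        p = np.array([0.04, 0.001, 0.9, 0.02])
        adj = bh_adjust(p)
        # order statistic check: ranks of adjusted match ranks of raw
        assert list(np.argsort(adj)) == list(np.argsort(p))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_adjusted_never_below_raw_and_monotone(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestRunMediationBattery:
    def test_battery_size_252_per_component(self, default_cohort):
        ci = default_cohort["clinical"]["group"] == "CI"
        pca = run_pca(default_cohort["clinical"])
        battery = run_mediation_battery(
            pca.scores,
            default_cohort["connectivity"].loc[ci],
            default_cohort["reading"].loc[ci],
            n_boot=20,
            seed=0,
        )
        per_pc = battery.groupby("predictor").size()
        assert (per_pc == 252).all()
        assert len(battery) == 252 * pca.n_retained

    def test_null_cohort_controls_false_discoveries(self):
        sig_fracs = []
        for seed in range(8):
            c = generate_cohort(CohortSpec(mediation_effects=[], seed=seed))
            ci = c["clinical"]["group"] == "CI"
            pca = run_pca(c["clinical"])
            battery = run_mediation_battery(
                pca.scores,
                c["connectivity"].loc[ci],
                c["reading"].loc[ci],
                n_boot=200,
                seed=seed,
            )
            sig_fracs.append(battery["significant"].mean())
        assert np.mean(sig_fracs) <= 0.05

    def test_misaligned_subjects_rejected(self, default_cohort):
        pca = run_pca(default_cohort["clinical"])
        reading = default_cohort["reading"].iloc[:3]
        with pytest.raises(KeyError):
            run_mediation_battery(
                pca.scores,
                default_cohort["connectivity"],
                reading,
                n_boot=10,
            )

    def test_bh_applied_within_each_component(self, default_cohort):
        ci = default_cohort["clinical"]["group"] == "CI"
        pca = run_pca(default_cohort["clinical"])
        battery = run_mediation_battery(
            pca.scores,
            default_cohort["connectivity"].loc[ci],
            default_cohort["reading"].loc[ci],
            n_boot=50,
            seed=1,
        )
        for _, fam in battery.groupby("predictor"):
            np.testing.assert_allclose(
                fam["p_bh"].to_numpy(),
                bh_adjust(fam["p_raw"].to_numpy()),
                atol=1e-12,
            )
        assert (battery["p_bh"] >= battery["p_raw"] - 1e-12).all()


class TestCompareGroups:
    def _frame(self, x, y):
        return pd.DataFrame(
            {
                "group": ["CI"] * len(x) + ["TH"] * len(y),
                "WRDC": np.concatenate([x, y]),
            }
        )

    def test_identical_groups_give_null_statistics(self):
        vals = np.array([240.0, 250.0, 260.0, 245.0])
        out = compare_groups(self._frame(vals, vals))
        assert out.loc[0, "welch_t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "welch_p"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc[0, "mannwhitney_u"] == pytest.approx(len(vals) ** 2 / 2)

    def test_fully_separated_groups_give_u_zero(self):
        out = compare_groups(self._frame([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]))
        assert out.loc[0, "mannwhitney_u"] == 0.0

    def test_power_against_one_sd_shift(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sims = 100
        for _ in range(n_sims):
            x = rng.normal(250, 15, size=50)
            y = rng.normal(265, 15, size=25)
            out = compare_groups(self._frame(x, y))
            rejections += out.loc[0, "welch_p"] < 0.05
        assert rejections >= 0.8 * n_sims

    def test_group_with_one_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            compare_groups(self._frame([250.0], [240.0, 260.0]))

    def test_synthetic_cohort_th_scores_higher(self, default_cohort):
        out = compare_groups(default_cohort["reading"])
        # group_a = CI, group_b = TH; TH means are planted higher
        assert (out["mean_b"] > out["mean_a"]).all()


class TestFitReadingRegression:
    def test_exact_linear_relation_gives_r2_one(self):
        x = np.linspace(0, 10, 40)
        reading = pd.DataFrame({"WRDC": 3 * x + 2})
        predictors = pd.DataFrame({"age": x}, index=reading.index)
        out = fit_reading_regression(reading, predictors)
        assert out.loc[0, "r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc[0, "slope_age"] == pytest.approx(3.0, abs=1e-10)

    def test_null_relation_r2_near_expected_small_value(self):
        rng = np.random.default_rng(1)
        n = 1000
        reading = pd.DataFrame({"WRDC": rng.standard_normal(n)})
        predictors = pd.DataFrame({"x": rng.standard_normal(n)}, index=reading.index)
        out = fit_reading_regression(reading, predictors)
        assert out.loc[0, "r_squared"] < 0.01  # E[R^2] = k/(n-1) = 0.001

    def test_planted_r2_calibration(self):
        rng = np.random.default_rng(2)
        r2s = []
        for _ in range(100):
            n = 50
            x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
            signal = 2 * x1 - 1 * x2
            noise_sd = np.sqrt(signal.var() * 3)  # R^2 = 0.25
            y = signal + noise_sd * rng.standard_normal(n)
            reading = pd.DataFrame({"WRDC": y})
            predictors = pd.DataFrame({"x1": x1, "x2": x2}, index=reading.index)
            out = fit_reading_regression(reading, predictors)
            r2s.append(out.loc[0, "r_squared"])
        assert np.mean(r2s) == pytest.approx(0.25, abs=0.05)

    def test_collinear_predictors_rejected(self):
        x = np.linspace(0, 1, 30)
        reading = pd.DataFrame({"WRDC": x})
        predictors = pd.DataFrame({"a": x, "b": 2 * x}, index=reading.index)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_reading_regression(reading, predictors)
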
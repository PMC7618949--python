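import numpy as np
import pandas as pd
import pytest
from scipy import stats

from restmeg.glm import (
    Contrast,
    build_design,
    chi_squared_sex_balance,
    fit_glm,
    maxt_permutation,
    residual_df_report,
    sex_counts_from_percent,
)


def make_records(n_per_group, groups=("HC", "AD"), seed=0, scanners=("A", "B")):
    rng = np.random.default_rng(seed)
    n = n_per_group * len(groups)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": np.repeat(groups, n_per_group),
            "age": rng.uniform(50, 80, n),
            "sex": [("M", "F")[i % 2] for i in range(n)],
            "scanner": [scanners[(i // 2) % len(scanners)] for i in range(n)],
            "gm_volume": rng.normal(620, 25, n),
        }
    )


class TestBuildDesign:
    def test_group_compare_column_count(self):
        design, contrasts = build_design(make_records(3), "group_compare")
        assert design.matrix.shape == (6, 6)  # 2 indicators + age,sex,scanner,gm
        assert len(contrasts) == 1

    def test_swapping_group_labels_negates_cope(self, rng):
        records = make_records(10)
        y = rng.standard_normal(20)
        d1, _ = build_design(records, "group_compare")
        swapped = records.copy()
        swapped["group"] = swapped["group"].map({"HC": "AD", "AD": "HC"})
        d2, _ = build_design(swapped, "group_compare")

        def hc_minus_ad(design):
            w = np.zeros(len(design.columns))
            w[design.column_index("group[HC]")] = 1.0
            w[design.column_index("group[AD]")] = -1.0
            return Contrast("HC-AD", w)

        f1 = fit_glm(y, d1, hc_minus_ad(d1))
        f2 = fit_glm(y, d2, hc_minus_ad(d2))
        assert f1.cope == pytest.approx(-f2.cope)

    def test_single_scanner_column_dropped_with_warning(self):
        records = make_records(5, scanners=("A",))
        with pytest.warns(UserWarning, match="scanner"):
            design, _ = build_design(records, "ageing")
        assert all("scanner" not in c for c in design.columns)

    def test_missing_covariate_rejected(self):
        records = make_records(5)
        records.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="missing covariates"):
            build_design(records, "ageing")

    def test_slope_design_has_per_group_age_columns(self):
        design, contrasts = build_design(make_records(6), "beta_ageing_by_group")
        assert "age:HC" in design.columns and "age:AD" in design.columns
        assert contrasts[0].name == "age:HC-age:AD"


class TestFitGLM:
    def test_two_group_contrast_equals_pooled_t(self, rng):
        y = np.r_[rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)]
        X = np.column_stack([np.r_[np.ones(12), np.zeros(12)], np.r_[np.zeros(12), np.ones(12)]])
        fit = fit_glm(y, X, Contrast("A-B", [1, -1]))
        t = stats.ttest_ind(y[:12], y[12:])
        assert fit.cope == pytest.approx(y[:12].mean() - y[12:].mean())
        assert fit.t == pytest.approx(t.statistic)
        assert fit.df == 22

    def test_matches_statsmodels_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 40
        X = np.column_stack([np.ones(n), rng.uniform(50, 80, n), rng.standard_normal(n)])
        y = 0.1 * X[:, 1] + rng.standard_normal(n)
        fit = fit_glm(y, X, Contrast("age", [0, 1, 0]))
        res = sm.OLS(y, X).fit()
        assert fit.cope == pytest.approx(res.params[1])
        assert fit.t == pytest.approx(res.tvalues[1])

    def test_age_slope_recovered_with_nominal_coverage(self):
        # y = 0.3*age + noise; the 2-SE interval should cover 0.3 ~95% of
        # the time.
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            age = rng.uniform(50, 80, 200)
            y = 0.3 * age + rng.standard_normal(200)
            X = np.column_stack([np.ones(200), age])
            fit = fit_glm(y, X, Contrast("age", [0, 1]))
            hits += abs(fit.cope - 0.3) <= 2 * fit.se
        assert hits >= 90

    def test_zero_residual_variance_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = 2.0 + 3.0 * np.arange(6.0)  # exactly in the column space
        with pytest.raises(ValueError, match="residual"):
            fit_glm(y, X, Contrast("slope", [0, 1]))


class TestMaxTPermutation:
    def _design(self, n_per=15, seed=0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per
        X = np.column_stack(
            [
                np.r_[np.ones(n_per), np.zeros(n_per)],
                np.r_[np.zeros(n_per), np.ones(n_per)],
                rng.uniform(-15, 15, n),
            ]
        )
        return X, Contrast("A-B", [1, -1, 0])

    def test_extreme_effect_attains_minimum_p(self, rng):
        X, c = self._design()
        y = X[:, 0] * 100 + rng.standard_normal(30) * 0.01
        res = maxt_permutation(y, X, c, n_perm=500, seed=3)
        assert res.p_fwe[0] == pytest.approx(1 / 501)

    def test_corrected_p_dominates_single_cell_p(self, rng):
        X, c = self._design()
        Y = rng.standard_normal((30, 8))
        Y[:, 0] += X[:, 0] * 2.0
        joint = maxt_permutation(Y, X, c, n_perm=300, seed=4)
        for j in range(8):
            single = maxt_permutation(Y[:, j], X, c, n_perm=300, seed=4)
            assert joint.p_fwe[j] >= single.p_fwe[0] - 1e-12

    def test_injected_effect_only_significant_where_injected(self, rng):
        X, c = self._design()
        Y = rng.standard_normal((30, 6))
        Y[:, 2] += X[:, 0] * 3.0
        res = maxt_permutation(Y, X, c, n_perm=500, seed=5)
        assert res.p_fwe[2] < 0.05
        assert res.p_fwe[np.arange(6) != 2].min() > 0.05

    def test_invariant_under_joint_row_permutation(self, rng):
        X, c = self._design()
        Y = rng.standard_normal((30, 5))
        perm = rng.permutation(30)
        r1 = maxt_permutation(Y, X, c, n_perm=200, seed=6)
        r2 = maxt_permutation(Y[perm], X[perm], c, n_perm=200, seed=6)
        assert np.allclose(r1.copes, r2.copes)
        assert np.allclose(r1.ts, r2.ts)

    def test_seed_convergence_at_many_permutations(self, rng):
        X, c = self._design()
        Y = rng.standard_normal((30, 5))
        Y[:, 1] += X[:, 0] * 1.2
        r1 = maxt_permutation(Y, X, c, n_perm=5000, seed=1)
        r2 = maxt_permutation(Y, X, c, n_perm=5000, seed=2)
        assert np.all(np.abs(r1.p_fwe - r2.p_fwe) < 0.01)

    def test_tiny_n_warns_about_exhausted_permutations(self, rng):
        X = np.column_stack([np.ones(4), np.r_[1.0, 2.0, 3.0, 4.0]])
        y = rng.standard_normal(4)
        with pytest.warns(UserWarning, match="distinct permutations"):
            maxt_permutation(y, X, Contrast("x", [0, 1]), n_perm=100, seed=0)


class TestDfReport:
    def test_operative_df_is_n_minus_rank(self, rng):
        X = np.column_stack([np.ones(191), rng.standard_normal((191, 7))])
        rep = residual_df_report(191, X, n_comparisons=1)
        assert rep["rank"] == 8
        assert rep["operative_df"] == 183

    def test_intercept_only(self):
        rep = residual_df_report(20, np.ones((20, 1)), n_comparisons=1)
        assert rep["operative_df"] == 19

    def test_formula_echo_arithmetic(self):
        rep = residual_df_report(191, np.ones((191, 4)), n_comparisons=4)
        assert rep["formula_df"] == 191 - (4 + 4 - 1 + 1)


class TestChiSquared:
    def test_reconstructed_cohort_table(self):
        counts = sex_counts_from_percent(
            [29, 25, 33, 114, 77], [48.3, 60.0, 57.6, 57.9, 49.3]
        )
        assert counts.tolist() == [[14, 15], [15, 10], [19, 14], [66, 48], [38, 39]]
        chi2, df = chi_squared_sex_balance(counts)
        assert chi2 == pytest.approx(2.23, abs=0.02)
        assert df == 4

    def test_proportional_table_gives_zero(self):
        chi2, df = chi_squared_sex_balance([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_sex_balance([[0, 0], [5, 5]])
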
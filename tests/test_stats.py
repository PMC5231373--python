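"""Design-of-experiments statistics: ANOVA, MANOVA, Tukey, bootstrap, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest

from droprelax.stats import (
    anova_additive,
    beta_interval,
    bootstrap_ci,
    boxplot_outliers,
    manova_pillai,
    origin_regression,
    relaxation_time_intervals,
    tukey_hsd,
    validate_factor_table,
)


def random_balanced_table(rng, response_cols=("lambda_c",)):
    rows = []
    for mag, d, proc in itertools.product(
        ("area", "ar", "major"), range(1, 6), ("elongation", "recovery")
    ):
        row = {"magnitude": mag, "droplet": d, "process": proc}
        for col in response_cols:
            row[col] = float(rng.normal(10, 3))
        rows.append(row)
    return pd.DataFrame(rows)


class TestAnovaAdditive:
    def test_sums_of_squares_match_statsmodels_oracle(self, rng):
        table = random_balanced_table(rng)
        got = anova_additive(table)
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        ref = anova_lm(
            ols("lambda_c ~ C(magnitude) + C(droplet) + C(process)", table).fit(), typ=1
        )
        for mine, theirs in [("magnitude", "C(magnitude)"), ("droplet", "C(droplet)"),
                             ("process", "C(process)"), ("residual", "Residual")]:
            assert got.loc[mine, "sum_sq"] == pytest.approx(
                ref.loc[theirs, "sum_sq"], rel=1e-10
            )

    def test_decomposition_sums_to_total(self, rng):
        table = random_balanced_table(rng)
        got = anova_additive(table)
        total = ((table["lambda_c"] - table["lambda_c"].mean()) ** 2).sum()
        assert got["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_degrees_of_freedom_partition(self, rng):
        got = anova_additive(random_balanced_table(rng))
        assert got["df"].tolist() == [2, 4, 1, 22]
        assert got["df"].sum() == 29

    def test_constant_response_gives_zero_sums_of_squares(self, rng):
        table = random_balanced_table(rng)
        table["lambda_c"] = 7.0
        got = anova_additive(table)
        assert np.allclose(got["sum_sq"], 0.0)

    def test_unbalanced_table_rejected(self, rng):
        table = random_balanced_table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced|levels"):
            anova_additive(table)


class TestManovaPillai:
    def test_matches_statsmodels_manova_on_published_table(self, table1):
        got = manova_pillai(table1)
        from statsmodels.multivariate.manova import MANOVA

        ref = MANOVA.from_formula(
            "a + b + lambda_c + beta ~ C(magnitude) + C(droplet) + C(process)", table1
        ).mv_test()
        for mine, theirs in [("magnitude", "C(magnitude)"), ("droplet", "C(droplet)"),
                             ("process", "C(process)")]:
            ref_v = ref.results[theirs]["stat"].loc["Pillai's trace", "Value"]
            assert got.loc[mine, "pillai"] == pytest.approx(float(ref_v), abs=1e-6)

    def test_single_response_reduces_to_univariate_f(self, table1):
        man = manova_pillai(table1, responses=("lambda_c",))
        aov = anova_additive(table1, "lambda_c")
        for f in ("magnitude", "droplet", "process"):
            assert man.loc[f, "approx_f"] == pytest.approx(
                aov.loc[f, "f_value"], abs=1e-8
            )
            assert man.loc[f, "p_value"] == pytest.approx(
                aov.loc[f, "p_value"], abs=1e-8
            )

    def test_identical_response_vectors_give_zero_pillai(self, rng):
        table = random_balanced_table(rng, response_cols=("a", "b", "lambda_c", "beta"))
        for col in ("a", "b", "lambda_c", "beta"):
            table[col] = {"a": 1.0, "b": 2.0, "lambda_c": 3.0, "beta": 4.0}[col]
        got = manova_pillai(table)
        assert np.allclose(got["pillai"], 0.0)

    def test_pillai_within_bounds_and_label_permutation_invariant(self, table1):
        got = manova_pillai(table1)
        for f, df_h in [("magnitude", 2), ("droplet", 4), ("process", 1)]:
            assert 0 <= got.loc[f, "pillai"] <= min(df_h, 4)
        permuted = table1.copy()
        permuted["droplet"] = permuted["droplet"].map({1: 3, 2: 5, 3: 1, 4: 2, 5: 4})
        got_p = manova_pillai(permuted)
        assert got_p.loc["droplet", "pillai"] == pytest.approx(
            got.loc["droplet", "pillai"], abs=1e-10
        )


class TestTukeyHsd:
    def test_identical_groups_give_zero_diff_unit_p(self, rng):
        table = random_balanced_table(rng)
        base = table[table.droplet == 1]["lambda_c"].to_numpy()
        for d in range(2, 6):
            table.loc[table.droplet == d, "lambda_c"] = base
        got = tukey_hsd(table)
        assert np.allclose(got["diff"], 0.0)
        assert np.allclose(got["p_adj"], 1.0)

    def test_intervals_contain_diff_with_constant_half_width(self, table1):
        got = tukey_hsd(table1)
        assert np.all(got["lower"] <= got["diff"])
        assert np.all(got["diff"] <= got["upper"])
        widths = (got["upper"] - got["lower"]).to_numpy()
        assert np.allclose(widths, widths[0], rtol=1e-12)

    def test_single_level_factor_rejected(self, table1):
        table = table1[table1.process == "elongation"].copy()
        table["process"] = "elongation"
        with pytest.raises(ValueError):
            tukey_hsd(table1.assign(droplet=1), factor="droplet")


class TestBoxplotOutliers:
    def test_published_beta_values_flag_exactly_three(self, table1):
        out, kept, fences = boxplot_outliers(table1["beta"])
        assert sorted(out.tolist()) == [4.10, 4.95, 12.0]
        assert len(kept) == 27

    def test_tight_spread_has_no_outliers(self):
        out, kept, _ = boxplot_outliers(list(range(1, 11)))
        assert out.size == 0 and kept.size == 10

    def test_single_huge_value_is_flagged(self):
        out, _, _ = boxplot_outliers(list(range(1, 11)) + [1000.0])
        assert out.tolist() == [1000.0]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            boxplot_outliers([1.0, 2.0, 3.0])


class TestBootstrapCI:
    def test_constant_sample_gives_degenerate_interval(self):
        ci = bootstrap_ci([5.0] * 10, seed=3)
        assert ci.lower == ci.upper == 5.0

    def test_same_seed_is_bit_reproducible(self, rng):
        x = rng.normal(size=20)
        a = bootstrap_ci(x, seed=11)
        b = bootstrap_ci(x, seed=11)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_nominal_coverage_on_gaussian_samples(self):
        rng = np.random.default_rng(99)
        covered = 0
        for _ in range(200):
            x = rng.normal(size=15)
            ci = bootstrap_ci(x, n_resamples=1000, seed=int(rng.integers(2**31)))
            covered += ci.lower <= 0.0 <= ci.upper
        assert 0.90 * 200 <= covered <= 0.99 * 200

    def test_beta_interval_removes_outliers_first(self, table1):
        ci, out = beta_interval(table1, seed=1)
        assert sorted(out.tolist()) == [4.10, 4.95, 12.0]
        assert 1.2 < ci.lower < ci.upper < 1.9

    def test_process_intervals_overlap_for_published_times(self, table1):
        cis = relaxation_time_intervals(table1, seed=2)
        assert set(cis) == {"elongation", "recovery"}
        assert cis["elongation"].overlaps(cis["recovery"])


class TestOriginRegression:
    def test_exact_proportional_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        fit = origin_regression(x, 2 * x)
        assert fit.intercept is None
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_pure_offset_keeps_intercept(self):
        x = np.array([1.0, 2, 3, 4, 5])
        fit = origin_regression(x, np.full(5, 3.0))
        assert fit.intercept is not None
        assert fit.intercept == pytest.approx(3.0, abs=1e-10)

    def test_through_origin_slope_matches_closed_form(self, rng):
        x = rng.uniform(1, 10, size=25)
        y = 0.85 * x + rng.normal(scale=1.5, size=25)
        fit = origin_regression(x, y)
        if fit.intercept is None:
            expected = float(np.sum(x * y) / np.sum(x**2))
            assert fit.slope == pytest.approx(expected, abs=1e-12)

    def test_zero_x_rejected(self):
        with pytest.raises(ValueError):
            origin_regression([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])


def test_validate_factor_table_passes_on_fixture(table1):
    validate_factor_table(table1)
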
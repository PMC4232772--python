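"""Shrinkage-F model fitting, variance shrinkage, and permutation p-values,
checked against hand calculations and independent enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, polygamma
from scipy.stats import f_oneway, kstest

from moltset.de_stats import (
    StageDesign,
    fit_stage_model,
    fold_changes,
    fs_statistics,
    permutation_pvalues,
    run_de,
    shrink_variances,
)
from moltset.matrix import ExpressionMatrix


def make_two_group(values, n_a):
    """Matrix from a features x samples array; first n_a columns are group A."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    samples = [f"s{j}" for j in range(n)]
    states = {s: ("A" if j < n_a else "B") for j, s in enumerate(samples)}
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=[f"f{i:03d}" for i in range(values.shape[0])], columns=samples),
        states,
    )
    design = StageDesign("AvB", tuple(samples[:n_a]), tuple(samples[n_a:]))
    return matrix, design


class TestFitStageModel:
    def test_hand_worked_decomposition(self, two_group_matrix, two_group_design):
        # A=(1,2,3), B=(3,4,5): means (2,4), RSS=4 on 4 df, between-SS=6
        fit = fit_stage_model(two_group_matrix, two_group_design)
        assert fit.mean_a[0] == pytest.approx(2.0)
        assert fit.mean_b[0] == pytest.approx(4.0)
        assert fit.rss[0] == pytest.approx(4.0)
        assert fit.between_ss[0] == pytest.approx(6.0)
        assert fit.nu == 4
        assert fit.q == 1

    def test_constant_feature_has_zero_sums_of_squares(self):
        matrix, design = make_two_group([[7.0] * 6], n_a=3)
        fit = fit_stage_model(matrix, design)
        assert fit.rss[0] == 0.0
        assert fit.between_ss[0] == 0.0

    def test_residuals_sum_to_zero_within_groups(self):
        rng = np.random.default_rng(0)
        matrix, design = make_two_group(rng.normal(size=(50, 7)), n_a=3)
        fit = fit_stage_model(matrix, design)
        np.testing.assert_allclose(fit.residuals[:, :3].sum(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.residuals[:, 3:].sum(axis=1), 0.0, atol=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            StageDesign("bad", ("a",), ("b", "c"))


class TestShrinkVariances:
    def test_identical_variances_fully_pooled(self):
        rss = np.full(20, 3.0)
        out = shrink_variances(rss, nu=4)
        np.testing.assert_allclose(out, out[0])
        # degenerate dispersion: estimate is the common value times the
        # log-scale bias correction
        m = digamma(2.0) + math.log(2.0) - math.log(4.0)
        assert out[0] == pytest.approx((3.0 / 4.0) * math.exp(-m))

    def test_large_dispersion_approaches_no_shrinkage(self):
        # spread the log variances so widely that the James-Stein factor -> 1
        # (staying above the variance floor)
        nu = 4
        x = np.linspace(-15.0, 15.0, 100)
        rss = np.exp(x) * nu
        out = shrink_variances(rss, nu=nu)
        m = digamma(nu / 2.0) + math.log(2.0) - math.log(nu)
        raw_corrected = (rss / nu) * math.exp(-m)
        # c = 1 - V_nu/var(x) ~ 0.991 here: log-scale deviation <= 0.13
        np.testing.assert_allclose(out, raw_corrected, rtol=0.15)
        # and the shrinkage factor itself is close to 1
        log_ratio = np.log(out / raw_corrected)
        assert 1.0 - np.max(np.abs(log_ratio)) / 15.0 > 0.98

    @pytest.mark.parametrize("seed", range(5))
    def test_mse_beats_raw_estimates(self, seed):
        # Monte-Carlo oracle: chi-square draws around a common true variance
        rng = np.random.default_rng(seed)
        nu, n_features, true_var = 4, 1000, 1.0
        rss = true_var * rng.chisquare(nu, size=n_features)
        raw = rss / nu
        shrunk = shrink_variances(rss, nu=nu)
        mse_raw = np.mean((raw - true_var) ** 2)
        mse_shrunk = np.mean((shrunk - true_var) ** 2)
        assert mse_shrunk < mse_raw

    def test_few_features_fall_back_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="moltset.de_stats"):
            out = shrink_variances(np.array([1.0, 2.0, 3.0]), nu=4)
        assert "unshrunk" in caplog.text
        m = digamma(2.0) + math.log(2.0) - math.log(4.0)
        np.testing.assert_allclose(out, (np.array([1.0, 2.0, 3.0]) / 4.0) * math.exp(-m))

    def test_zero_rss_floored_positive(self):
        out = shrink_variances(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), nu=3)
        assert (out > 0).all()


class TestFsStatistics:
    def test_classical_equivalence_on_random_features(self):
        # with shrinkage disabled, Fs is the textbook one-way ANOVA F
        rng = np.random.default_rng(42)
        vals = rng.normal(size=(1000, 8))
        matrix, design = make_two_group(vals, n_a=4)
        fit = fit_stage_model(matrix, design)
        fs = fs_statistics(fit, fit.rss / fit.nu)
        f_ref = f_oneway(vals[:, :4], vals[:, 4:], axis=1).statistic
        np.testing.assert_allclose(fs, f_ref, rtol=1e-10)

    def test_worked_example_classical_f_is_six(self, two_group_matrix, two_group_design):
        fit = fit_stage_model(two_group_matrix, two_group_design)
        fs = fs_statistics(fit, fit.rss / fit.nu)
        assert fs[0] == pytest.approx(6.0, rel=1e-12)

    def test_zero_between_ss_gives_zero_fs(self):
        matrix, design = make_two_group([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]], n_a=3)
        fit = fit_stage_model(matrix, design)
        fs = fs_statistics(fit, fit.rss / fit.nu)
        assert fs[0] == 0.0

    def test_scale_equivariance(self):
        # scaling all deviations from the grand mean scales numerator and
        # denominator together: F is unchanged
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(20, 6))
        grand = vals.mean(axis=1, keepdims=True)
        scaled = grand + 2.0 * (vals - grand)
        for block in (vals, scaled):
            matrix, design = make_two_group(block, n_a=3)
            fit = fit_stage_model(matrix, design)
            fs = fs_statistics(fit, fit.rss / fit.nu)
            if block is vals:
                first = fs
        np.testing.assert_allclose(fs, first, rtol=1e-10)


def oracle_label_enumeration(vals, n_a, *, shrink, pool):
    """Independent oracle: enumerate group-A label assignments directly.

    Recomputes F (optionally with log-scale James-Stein shrinkage across
    features, re-estimated per assignment) for every way of assigning n_a of
    the columns to group A, and counts assignments with F* >= F observed —
    per feature, or pooled over all (assignment, feature) pairs.
    """
    vals = np.asarray(vals, dtype=float)
    n_features, n = vals.shape
    nu = n - 2

    def stats_for(cols_a):
        cols_a = list(cols_a)
        cols_b = [j for j in range(n) if j not in cols_a]
        a, b = vals[:, cols_a], vals[:, cols_b]
        ma, mb = a.mean(1), b.mean(1)
        grand = (len(cols_a) * ma + len(cols_b) * mb) / n
        between = len(cols_a) * (ma - grand) ** 2 + len(cols_b) * (mb - grand) ** 2
        rss = ((a - ma[:, None]) ** 2).sum(1) + ((b - mb[:, None]) ** 2).sum(1)
        if shrink and n_features > 3:
            x = np.log(np.maximum(rss / nu, 1e-8))
            xbar = x.mean()
            ss = ((x - xbar) ** 2).sum()
            c = max(0.0, 1.0 - (n_features - 3) * polygamma(1, nu / 2.0) / ss) if ss > 0 else 0.0
            bias = math.exp(-(digamma(nu / 2.0) + math.log(2.0) - math.log(nu)))
            sigma2 = np.exp(xbar + c * (x - xbar)) * bias
        else:
            bias = math.exp(-(digamma(nu / 2.0) + math.log(2.0) - math.log(nu)))
            sigma2 = np.maximum(rss / nu, 1e-8)
            if shrink:
                sigma2 = sigma2 * bias
        return between / sigma2

    f_obs = stats_for(range(n_a))
    assignments = list(itertools.combinations(range(n), n_a))
    count = np.zeros(n_features, dtype=np.int64)
    for cols_a in assignments:
        f_star = stats_for(cols_a)
        if pool:
            pool_sorted = np.sort(f_star, axis=None)
            count += pool_sorted.size - np.searchsorted(pool_sorted, f_obs, side="left")
        else:
            count += f_star >= f_obs
    denom = len(assignments) * (n_features if pool else 1)
    return count / denom


class TestPermutationPvalues:
    def test_exhaustive_2v2_worked_example(self):
        # A=(1,2), B=(3,5): 2 of the 6 label assignments reach F >= 5
        matrix, design = make_two_group([[1.0, 2.0, 3.0, 5.0]], n_a=2)
        p = permutation_pvalues(matrix, design, exhaustive=True)
        assert p[0] == pytest.approx(1.0 / 3.0, abs=1e-15)

    def test_constant_feature_p_is_one(self):
        matrix, design = make_two_group(
            np.vstack([[np.full(6, 4.0)], np.random.default_rng(1).normal(size=(1, 6))]), n_a=3
        )
        p = permutation_pvalues(matrix, design, n_perm=50, seed=0, pool=False)
        assert p[0] == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (3, 3), (2, 4)])
    @pytest.mark.parametrize("pool", [False, True])
    @pytest.mark.parametrize("shrink", [False, True])
    def test_exhaustive_matches_enumeration_oracle(self, n_a, n_b, pool, shrink):
        rng = np.random.default_rng(n_a * 10 + n_b + 7 * pool + 13 * shrink)
        vals = rng.normal(size=(20, n_a + n_b))
        matrix, design = make_two_group(vals, n_a=n_a)
        p_impl = permutation_pvalues(
            matrix, design, exhaustive=True, pool=pool, shrink=shrink
        )
        p_oracle = oracle_label_enumeration(vals, n_a, shrink=shrink, pool=pool)
        np.testing.assert_array_equal(p_impl, p_oracle)

    def test_shift_invariance_per_feature(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(30, 6))
        shifted = vals.copy()
        shifted[7] += 100.0  # add a constant to all samples of one feature
        p1 = permutation_pvalues(*make_two_group(vals, 3), n_perm=100, seed=9)
        p2 = permutation_pvalues(*make_two_group(shifted, 3), n_perm=100, seed=9)
        np.testing.assert_allclose(p1, p2)

    def test_monotone_in_observed_fs(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(100, 6))
        matrix, design = make_two_group(vals, n_a=3)
        res = run_de(matrix, design, n_perm=100, seed=2, recompute_shrinkage=False)
        ordered = res.sort_values("Fs", ascending=False)
        assert ordered["p_raw"].is_monotonic_increasing

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(size=(300, 6))
        matrix, design = make_two_group(vals, n_a=3)
        p = permutation_pvalues(matrix, design, n_perm=200, seed=4)
        # KS critical value at alpha=0.01 for n=300 is ~1.63/sqrt(300)
        assert kstest(p, "uniform").statistic < 1.63 / math.sqrt(300)

    def test_invalid_n_perm(self):
        matrix, design = make_two_group(np.zeros((2, 4)), n_a=2)
        with pytest.raises(ValueError):
            permutation_pvalues(matrix, design, n_perm=0)


class TestFoldChanges:
    def test_definition_and_direction(self):
        matrix, design = make_two_group([[4.0, 4.0, 2.0, 2.0], [2.0, 2.0, 4.0, 4.0], [3.0, 3.0, 3.0, 3.0]], n_a=2)
        fit = fit_stage_model(matrix, design)
        fc = fold_changes(fit)
        assert fc["log2fc"].tolist() == [2.0, -2.0, 0.0]
        assert fc["fold"].tolist() == [4.0, 4.0, 1.0]
        assert fc["direction"].tolist() == ["up", "down", "down"]
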
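"""Statistics: PCA composites, correlations, SMA, trimming, ex-Gaussian, Wilcoxon."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vocspan.stats import (
    build_correlation_tables,
    condition_contrasts,
    correlate,
    correlation_table_frame,
    fit_exgaussian,
    geometric_mean_rt,
    pca_composite,
    sma_fit,
    trim_outliers,
    wilcoxon_signed_rank,
)


def data_with_exact_correlation(R: np.ndarray, n: int, rng) -> np.ndarray:
    """Data whose *sample* correlation matrix equals R exactly.

    Whiten a random draw (making its sample covariance the identity), then
    color it with the Cholesky factor of R.
    """
    k = R.shape[0]
    X = rng.standard_normal((n, k))
    X -= X.mean(axis=0)
    cov = X.T @ X / (n - 1)
    vals, vecs = np.linalg.eigh(cov)
    white = X @ vecs @ np.diag(vals**-0.5) @ vecs.T
    return white @ np.linalg.cholesky(R).T


class TestPCA:
    def test_identical_columns_are_rank_one(self, rng):
        col = rng.standard_normal(40)
        table = np.column_stack([col, col, col])
        model = pca_composite(table)
        assert np.allclose(model.eigenvalues, [3.0, 0.0, 0.0], atol=1e-10)
        assert np.allclose(model.variance_explained, [1.0, 0.0, 0.0], atol=1e-10)
        assert model.retained == (0,)

    def test_equicorrelation_closed_form(self, rng):
        r = 0.715
        R = np.full((3, 3), r)
        np.fill_diagonal(R, 1.0)
        model = pca_composite(data_with_exact_correlation(R, 50, rng))
        # eigenvalues of an equicorrelation matrix: 1 + (k-1)r, then 1 - r
        assert model.eigenvalues[0] == pytest.approx(1 + 2 * r, abs=1e-9)
        assert np.allclose(model.eigenvalues[1:], 1 - r, atol=1e-9)
        assert model.eigenvalues[0] == pytest.approx(2.43, abs=1e-9)

    def test_reconstructs_correlation_matrix(self, rng):
        data = rng.standard_normal((30, 5)) @ rng.standard_normal((5, 5))
        model = pca_composite(data)
        corr = np.corrcoef(data, rowvar=False)
        rebuilt = model.loadings @ np.diag(model.eigenvalues) @ model.loadings.T
        assert np.allclose(rebuilt, corr, atol=1e-8)
        assert model.eigenvalues.sum() == pytest.approx(5.0, abs=1e-9)

    def test_first_eigenvalue_matches_power_iteration(self, rng):
        for _ in range(5):
            data = rng.standard_normal((25, 6)) @ rng.standard_normal((6, 6))
            corr = np.corrcoef(data, rowvar=False)
            vec = np.ones(6)
            for _ in range(3000):
                vec = corr @ vec
                vec /= np.linalg.norm(vec)
            oracle = float(vec @ corr @ vec)
            model = pca_composite(data)
            assert model.eigenvalues[0] == pytest.approx(oracle, abs=1e-6)

    def test_scores_uncorrelated_and_signs_fixed(self, rng):
        data = rng.standard_normal((40, 4)) + rng.standard_normal((40, 1))
        model = pca_composite(data)
        score_corr = np.corrcoef(model.scores, rowvar=False)
        assert np.allclose(score_corr - np.diag(np.diag(score_corr)), 0, atol=1e-8)
        assert all(model.loadings[:, c].mean() >= 0
                   for c in range(model.loadings.shape[1]))

    def test_zero_variance_column_named(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                              "b": [5.0, 5.0, 5.0, 5.0],
                              "c": [2.0, 1.0, 4.0, 3.0]})
        with pytest.raises(ValueError, match="b"):
            pca_composite(table)

    def test_needs_more_rows_than_columns(self, rng):
        with pytest.raises(ValueError):
            pca_composite(rng.standard_normal((3, 3)))


class TestCorrelate:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(20)
        cell = correlate(x, x * 2 + 1, family_size=6)
        assert cell.coefficient == pytest.approx(1.0)
        assert cell.p_value < 1e-10
        assert cell.significant_bonferroni

    def test_spearman_perfect_negative(self, rng):
        x = rng.standard_normal(15)
        cell = correlate(x, -x**3, method="spearman", family_size=1)
        assert cell.coefficient == pytest.approx(-1.0)

    def test_spearman_p_matches_t_approximation(self, rng):
        """Independent t-approximation check at n = 32, rho near 0.35.

        A rank correlation of 0.35 in a sample of 32 sits right at the
        conventional significance boundary (p ≈ .05).
        """
        n = 32
        x = np.arange(n, dtype=float)
        rho_target = 0.35
        for seed in range(100):
            y = x + np.random.default_rng(seed).normal(0, 22, n)
            rho = sps.spearmanr(x, y).statistic
            if abs(rho - rho_target) < 0.005:
                break
        else:
            pytest.fail("no draw with rank correlation near 0.35")
        cell = correlate(x, y, method="spearman", family_size=1)
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p_oracle = 2 * sps.t.sf(abs(t), df=n - 2)
        assert cell.p_value == pytest.approx(p_oracle, abs=1e-6)
        assert 0.03 < cell.p_value < 0.08

    def test_bonferroni_threshold(self, rng):
        x = rng.standard_normal(20)
        cell = correlate(x, x + rng.standard_normal(20), family_size=8)
        assert cell.bonferroni_threshold == pytest.approx(0.05 / 8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], family_size=1)


class TestSMA:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        slope, intercept = sma_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_toy_slope_from_hand_computed_sds(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        slope, intercept = sma_fit(x, y)
        # sd(y) = sqrt(1.5), sd(x) = sqrt(5/3), r > 0 → slope = sqrt(0.9)
        assert slope == pytest.approx(np.sqrt(0.9), abs=1e-12)
        assert intercept == pytest.approx(2.5 - np.sqrt(0.9) * 2.5, abs=1e-12)

    def test_axis_swap_inverts_slope(self, rng):
        x = rng.standard_normal(30)
        y = 0.6 * x + 0.3 * rng.standard_normal(30)
        assert sma_fit(x, y)[0] * sma_fit(y, x)[0] == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(25)
        y = x + rng.standard_normal(25)
        base = sma_fit(x, y)[0]
        assert sma_fit(x, 7.5 * y)[0] == pytest.approx(7.5 * base)

    def test_zero_correlation_rejected(self):
        x = np.array([1.0, 2.0, 1.0, 2.0])
        y = np.array([1.0, 1.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            sma_fit(x, y)


class TestTrimOutliers:
    def test_constant_values_untouched(self):
        kept, n_removed = trim_outliers([400.0] * 20)
        assert n_removed == 0 and kept.size == 20

    def test_cascading_removal_over_two_passes(self):
        """Removing the extreme value exposes a second outlier.

        Hand-computed: with 98 values at 500 plus {800, 1200}, the first
        pass's threshold (~813) removes only 1200; recomputing tightens the
        threshold (~624) and removes 800; the third pass removes nothing.
        """
        values = [500.0] * 98 + [800.0, 1200.0]
        kept, n_removed = trim_outliers(values)
        assert n_removed == 2
        assert np.all(kept == 500.0)
        # loop-free oracle: apply the two passes explicitly
        arr = np.array(values)
        t1 = arr.mean() + 4 * arr.std(ddof=1)
        once = arr[arr <= t1]
        assert set(arr[arr > t1]) == {1200.0}
        t2 = once.mean() + 4 * once.std(ddof=1)
        assert set(once[once > t2]) == {800.0}

    def test_low_outlier_never_removed(self):
        values = [400.0] * 20 + [100.0]
        kept, n_removed = trim_outliers(values)
        assert n_removed == 0 and 100.0 in kept

    def test_output_subset_and_order_independent(self, rng):
        values = rng.exponential(200, 500) + 300
        kept_a, removed_a = trim_outliers(values)
        kept_b, removed_b = trim_outliers(values[::-1])
        assert removed_a == removed_b
        assert sorted(kept_a) == sorted(kept_b)
        assert np.isin(kept_a, values).all()

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            trim_outliers([500.0] * 9)


class TestExGaussian:
    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(99)
        mu, sigma, tau = 500.0, 50.0, 150.0
        rts = rng.normal(mu, sigma, 10_000) + rng.exponential(tau, 10_000)
        fit = fit_exgaussian(rts)
        assert fit.converged
        assert fit.mu == pytest.approx(mu, rel=0.05)
        assert fit.sigma == pytest.approx(sigma, rel=0.05)
        assert fit.tau == pytest.approx(tau, rel=0.05)
        # moment identities: E = mu + tau, Var = sigma^2 + tau^2
        assert fit.mean == pytest.approx(rts.mean(), rel=0.01)
        assert fit.variance == pytest.approx(rts.var(ddof=1), rel=0.05)

    def test_pure_gaussian_limit(self):
        rng = np.random.default_rng(7)
        rts = rng.normal(500.0, 50.0, 5000)
        fit = fit_exgaussian(rts)
        assert fit.mean == pytest.approx(rts.mean(), rel=0.01)

    def test_fit_is_local_maximum(self):
        rng = np.random.default_rng(11)
        rts = rng.normal(450, 40, 2000) + rng.exponential(120, 2000)
        fit = fit_exgaussian(rts)

        def loglik(mu, sigma, tau):
            return sps.exponnorm.logpdf(rts, K=tau / sigma, loc=mu,
                                        scale=sigma).sum()

        best = loglik(fit.mu, fit.sigma, fit.tau)
        for bump in ((5, 0, 0), (0, 5, 0), (0, 0, 5), (-5, 0, 0), (0, -5, 0)):
            perturbed = loglik(fit.mu + bump[0], fit.sigma + bump[1],
                               fit.tau + bump[2])
            assert best >= perturbed - 1e-6

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exgaussian([500.0] * 10)     # too few
        with pytest.raises(ValueError):
            fit_exgaussian([-1.0] * 100)     # non-positive


class TestGeometricMean:
    def test_constant(self):
        assert geometric_mean_rt([400.0] * 5) == pytest.approx(400.0)

    def test_two_point(self):
        assert geometric_mean_rt([100.0, 10_000.0]) == pytest.approx(1000.0)

    def test_never_exceeds_arithmetic_mean(self, rng):
        for _ in range(100):
            values = rng.exponential(300, 50) + 100
            assert geometric_mean_rt(values) <= values.mean() + 1e-9

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_rt([100.0, 0.0])


class TestWilcoxon:
    def exact_two_sided_p(self, diffs):
        """Enumerate all sign assignments of |diffs| (independent oracle)."""
        ranks = sps.rankdata(np.abs(diffs))
        n = len(diffs)
        mean_w = n * (n + 1) / 4
        observed = ranks[np.array(diffs) > 0].sum()
        count = 0
        for mask in range(2**n):
            w = sum(ranks[k] for k in range(n) if (mask >> k) & 1)
            if abs(w - mean_w) >= abs(observed - mean_w) - 1e-12:
                count += 1
        return count / 2**n

    def test_normal_approximation_close_to_exact_enumeration(self, rng):
        for _ in range(5):
            x = rng.normal(0.4, 1.0, 8)
            y = np.zeros(8)
            _, p_normal = wilcoxon_signed_rank(x, y)
            p_exact = self.exact_two_sided_p(x)
            assert abs(p_normal - p_exact) <= 0.03

    def test_one_sided_extreme_at_n32(self):
        x = np.arange(1.0, 33.0)
        # strictly increasing positive differences: all ranks distinct
        z, p = wilcoxon_signed_rank(x + 5.0 + 0.1 * x, x)
        # all 32 ranks on one side: Z = (528 - 264 - 0.5) / sqrt(32*33*65/24)
        assert z == pytest.approx(263.5 / np.sqrt(2860), abs=1e-9)
        assert z == pytest.approx(4.927, abs=1e-3)
        # identical differences tie every rank; the tie correction shrinks
        # the null variance by (32³ - 32)/48 and the Z grows accordingly
        z_tied, _ = wilcoxon_signed_rank(x + 5.0, x)
        assert z_tied == pytest.approx(263.5 / np.sqrt(2860 - 682), abs=1e-9)

    def test_antisymmetric_differences_near_zero(self):
        d = np.array([3.0, -3.0, 5.0, -5.0, 7.0, -7.0, 9.0, -9.0])
        z, p = wilcoxon_signed_rank(d, np.zeros(8))
        assert z == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_invariant_to_monotone_transform_of_differences(self, rng):
        x = rng.normal(0.3, 1.0, 20)
        z_raw, _ = wilcoxon_signed_rank(x, np.zeros(20))
        z_cubed, _ = wilcoxon_signed_rank(x**3, np.zeros(20))
        assert z_raw == pytest.approx(z_cubed, abs=1e-12)

    def test_matches_scipy_approximation(self, rng):
        x = rng.normal(0.5, 1.0, 30)
        z_ours, p_ours = wilcoxon_signed_rank(x, np.zeros(30))
        res = sps.wilcoxon(x, mode="approx", correction=True)
        assert p_ours == pytest.approx(res.pvalue, abs=1e-10)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(10), np.ones(10))


class TestContrastsAndTables:
    def test_identical_conditions_give_zero_contrast(self):
        table = pd.DataFrame({"16": [0.8, 0.9, 0.7, 0.85],
                              "8": [0.8, 0.9, 0.7, 0.85]})
        result = condition_contrasts(table, reference="16")
        assert result.loc["8", "mean_diff"] == 0.0
        assert result.loc["8", "t"] == 0.0

    def test_unbalanced_rejected(self):
        table = pd.DataFrame({"16": [0.8, np.nan], "8": [0.7, 0.6]})
        with pytest.raises(ValueError, match="incomplete"):
            condition_contrasts(table, reference="16")

    def test_grid_flags_and_missing_cells(self, rng):
        n = 20
        data = pd.DataFrame({
            "pred": rng.standard_normal(n),
            "sparse": [np.nan] * (n - 2) + [1.0, 2.0],
        })
        data["out"] = data["pred"]
        cells = build_correlation_tables(data, ["pred", "sparse"], ["out"],
                                         family_size=2)
        frame = correlation_table_frame(cells)
        same = frame[frame.predictor == "pred"].iloc[0]
        assert same.coefficient == pytest.approx(1.0)
        assert bool(same.significant_bonferroni)
        assert bool(frame[frame.predictor == "sparse"].iloc[0].missing)

    def test_permuted_covariate_is_null(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = x + 0.1 * rng.standard_normal(n)
        shuffled = rng.permutation(y)
        cell = correlate(x, shuffled, family_size=1)
        assert abs(cell.coefficient) < 0.2
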
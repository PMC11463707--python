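"""KS normality, TOST equivalence, F-test of variances, Bonferroni battery."""

import numpy as np
import pytest
from scipy import stats

from accowave.pca import fit_basis
from accowave.validation import (
    bonferroni_alpha,
    f_test_variances,
    ks_normality,
    tost_means,
    validate_cohorts,
)


@pytest.mark.parametrize(
    "alpha,m,expected",
    [(0.05, 150, 0.05 / 150), (0.05, 1, 0.05), (0.05, 49, 0.05 / 49)],
)
def test_bonferroni_arithmetic(alpha, m, expected):
    assert bonferroni_alpha(alpha, m) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_validation():
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni_alpha(1.5, 10)


class TestKSNormality:
    def test_accepts_normal_samples_in_most_replicates(self):
        accepted = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=10_000)
            if ks_normality(x) > 0.05:
                accepted += 1
        # conservative because the normal parameters are estimated
        assert accepted >= 94

    def test_rejects_gross_non_normality(self):
        x = np.array([0.0] * 49 + [1.0])
        assert ks_normality(x) < 1e-6

    def test_deterministic_and_degenerate(self):
        x = np.random.default_rng(5).normal(size=200)
        assert ks_normality(x) == ks_normality(x.copy())
        with pytest.warns(UserWarning):
            assert ks_normality(np.ones(10)) == 0.0
        with pytest.raises(ValueError):
            ks_normality(np.ones(3))


class TestTOST:
    def test_boundary_difference_gives_half(self, rng):
        # when the observed difference equals the margin exactly, the
        # upper one-sided t statistic is 0 -> p = 0.5
        x = rng.normal(size=500)
        x -= x.mean()
        y = x + 0.3  # same sample shifted: diff exactly 0.3, equal variances
        assert tost_means(x, y, 0.3) == pytest.approx(0.5, abs=1e-12)

    def test_identical_samples_strongly_equivalent(self, rng):
        x = rng.normal(size=5000)
        assert tost_means(x, x.copy(), 0.5 * x.std(ddof=1)) < 0.001

    def test_large_difference_not_equivalent(self, rng):
        x = rng.normal(size=300)
        assert tost_means(x, x + 5.0, 0.2) > 0.999

    def test_sign_symmetry(self, rng):
        x = rng.normal(0.3, 1, 200)
        y = rng.normal(0.1, 1.3, 400)
        assert tost_means(x, y, 0.4) == pytest.approx(tost_means(-x, -y, 0.4), abs=1e-12)

    def test_monotone_in_margin(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(0.1, 1, 200)
        assert tost_means(x, y, 0.15) >= tost_means(x, y, 0.3)

    def test_margin_validation(self, rng):
        with pytest.raises(ValueError):
            tost_means(rng.normal(size=10), rng.normal(size=10), 0.0)

    def test_cross_check_statsmodels(self, rng):
        from statsmodels.stats.weightstats import ttost_ind

        x = rng.normal(0.05, 1.1, 150)
        y = rng.normal(0.0, 0.9, 700)
        delta = 0.25
        p_ref = ttost_ind(x, y, -delta, delta, usevar="unequal")[0]
        assert tost_means(x, y, delta) == pytest.approx(float(p_ref), abs=1e-10)


class TestFTest:
    def test_equal_variances_equal_n(self, rng):
        x = rng.normal(size=100)
        y = x[::-1].copy()  # same sample variance
        assert f_test_variances(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_quadrupled_variance_detected(self, rng):
        x = rng.normal(0, 2.0, 191)
        y = rng.normal(0, 1.0, 191)
        assert f_test_variances(x, y) < 0.001

    def test_symmetry(self, rng):
        x = rng.normal(0, 1.2, 80)
        y = rng.normal(0, 0.8, 120)
        assert f_test_variances(x, y) == pytest.approx(f_test_variances(y, x), abs=1e-12)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            f_test_variances(np.ones(10), rng.normal(size=10))

    def test_null_pvalues_uniform(self):
        """Under equal variances and normality the two-sided F p-values
        are uniform on [0, 1]."""
        rng = np.random.default_rng(77)
        pvals = [
            f_test_variances(rng.normal(size=25), rng.normal(size=30))
            for _ in range(2000)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestValidateCohorts:
    def make_pair(self, rng, n=191, p=6):
        X = rng.normal(size=(n, p)) @ np.diag(np.linspace(2.0, 0.5, p))
        return X

    def test_copied_cohort_passes_everything(self, rng):
        X = self.make_pair(rng)
        basis = fit_basis(X, cutoff=1.0)
        rep_ev, rep_z = validate_cohorts(X, X.copy(), basis)
        assert rep_z.table["mean_equivalent"].all()
        assert rep_ev.table["mean_equivalent"].all()
        np.testing.assert_allclose(rep_z.table["f_p"], 1.0, atol=1e-12)
        assert rep_z.adjusted_alpha == pytest.approx(0.05 / X.shape[1])
        assert rep_ev.adjusted_alpha == pytest.approx(0.05 / basis.k)

    def test_doubled_sd_fails_f(self, rng):
        X = self.make_pair(rng, n=400)
        basis = fit_basis(X, cutoff=1.0)
        _, rep = validate_cohorts(X, 2.0 * X, basis)
        assert not rep.table["variance_equal"].any()

    def test_schema_mismatch_rejected(self, rng):
        X = self.make_pair(rng)
        basis = fit_basis(X, cutoff=1.0)
        with pytest.raises(ValueError):
            validate_cohorts(X, X[:, :-1], basis)

    def test_mask_excludes_imputed_cells_from_original_stats(self, rng):
        X = self.make_pair(rng)
        basis = fit_basis(X, cutoff=1.0)
        mask = np.zeros_like(X, dtype=bool)
        mask[:50, 0] = True
        _, rep = validate_cohorts(X, X.copy(), basis, original_mask=mask)
        expected = X[50:, 0].mean()
        assert rep.table["mean_original"].iloc[0] == pytest.approx(expected, abs=1e-12)
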
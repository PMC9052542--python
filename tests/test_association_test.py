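import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from tcrl import (
    fisher_combine,
    fit_null_h0,
    fit_null_h0prime,
    score_fixed,
    score_random_binary,
    score_random_continuous,
    tcrl_test,
)
from tcrl.association_test import ModelFitError, score_random
from tcrl.homology_kernel import SubstitutionScheme, build_kernel, psd_project
from tcrl.repertoire_io import CovariateTable, PhenotypeVector


def _design(n, rng):
    return np.column_stack([np.ones(n), rng.binomial(1, 0.5, n), rng.standard_normal(n)])


def _psd_kernel(n, rng):
    A = rng.standard_normal((n, n + 5))
    S = A @ A.T / (n + 5)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(314)


class TestFitNullH0:
    def test_continuous_intercept_only_closed_form(self, rng):
        y = rng.standard_normal(50) + 2.0
        X = np.ones((50, 1))
        fit = fit_null_h0(X, y, "continuous")
        np.testing.assert_allclose(fit.mu_tilde, np.full(50, y.mean()))
        np.testing.assert_allclose(fit.omega_diag, np.mean((y - y.mean()) ** 2))

    def test_binary_intercept_only_closed_form(self, rng):
        y = (rng.random(60) < 0.3).astype(float)
        fit = fit_null_h0(np.ones((60, 1)), y, "binary")
        np.testing.assert_allclose(fit.mu_tilde, y.mean(), atol=1e-8)

    @pytest.mark.parametrize("trait", ["continuous", "binary"])
    def test_gamma_annihilates_design(self, trait, rng):
        n = 80
        X = _design(n, rng)
        if trait == "continuous":
            y = X @ [0.1, 0.5, -0.4] + rng.standard_normal(n)
        else:
            y = rng.binomial(1, 1 / (1 + np.exp(-X @ [0.1, 0.5, -0.4]))).astype(float)
        fit = fit_null_h0(X, y, trait)
        assert np.abs(fit.Gamma @ X).max() < 1e-10

    def test_rank_deficient_design_errors(self, rng):
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ModelFitError):
            fit_null_h0(X, rng.standard_normal(30), "continuous")

    def test_one_class_binary_errors(self):
        with pytest.raises(ModelFitError):
            fit_null_h0(np.ones((20, 1)), np.zeros(20), "binary")


class TestScoreFixed:
    def test_feature_orthogonal_to_residuals_gives_zero_stat(self, rng):
        n = 60
        X = _design(n, rng)
        y = X @ [0.2, 0.1, 0.3] + rng.standard_normal(n)
        fit = fit_null_h0(X, y, "continuous")
        resid = y - fit.mu_tilde
        G = rng.standard_normal((n, 1))
        G -= resid[:, None] * (resid @ G) / (resid @ resid)  # orthogonalize
        stat, p = score_fixed(fit, G, y)
        assert stat == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels_lm_test_continuous(self, rng):
        n = 250
        X = _design(n, rng)
        G = rng.standard_normal((n, 2))
        y = X @ [0.1, 0.5, -0.4] + rng.standard_normal(n)
        stat, p = score_fixed(fit_null_h0(X, y, "continuous"), G, y)
        full = sm.OLS(y, np.hstack([X, G])).fit()
        lm_stat, lm_p, lm_df = full.compare_lm_test(sm.OLS(y, X).fit())
        assert stat == pytest.approx(lm_stat, rel=1e-9)
        assert p == pytest.approx(lm_p, rel=1e-9)
        assert lm_df == 2

    def test_matches_statsmodels_score_test_binary(self, rng):
        n = 250
        X = _design(n, rng)
        G = rng.standard_normal((n, 1)) + 0.2
        y = rng.binomial(1, 1 / (1 + np.exp(-X @ [0.1, 0.5, -0.4]))).astype(float)
        stat, p = score_fixed(fit_null_h0(X, y, "binary"), G, y)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        sm_stat, sm_p, _ = glm.score_test(exog_extra=G)
        assert stat == pytest.approx(float(np.ravel(sm_stat)[0]), rel=1e-8)
        assert p == pytest.approx(float(np.ravel(sm_p)[0]), rel=1e-8)

    def test_constant_feature_gives_singularity_error(self, rng):
        n = 40
        X = _design(n, rng)
        y = rng.standard_normal(n)
        fit = fit_null_h0(X, y, "continuous")
        with pytest.raises(ModelFitError, match="singular"):
            score_fixed(fit, np.ones((n, 1)), y)

    def test_permutation_null_pvalues_are_uniform(self, rng):
        n = 100
        X = _design(n, rng)
        y = X @ [0.1, 0.5, -0.4] + rng.standard_normal(n)
        fit = fit_null_h0(X, y, "continuous")
        G = rng.standard_normal(n)
        ps = []
        for _ in range(600):
            perm = rng.permutation(n)
            _, p = score_fixed(fit, G[perm, None], y)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFitNullH0prime:
    @pytest.mark.parametrize("trait", ["continuous", "binary"])
    def test_projection_identities(self, trait, rng):
        n = 90
        X = _design(n, rng)
        G = rng.standard_normal((n, 1))
        lp = X @ [0.1, 0.5, -0.4] + 0.3 * G[:, 0]
        if trait == "continuous":
            y = lp + rng.standard_normal(n)
        else:
            y = rng.binomial(1, 1 / (1 + np.exp(-lp))).astype(float)
        fit = fit_null_h0prime(X, G, y, trait)
        d = fit.dim_d
        assert d == 4
        assert np.trace(fit.P0) == pytest.approx(n - d, abs=1e-8)
        np.testing.assert_allclose(fit.P0 @ fit.P0, fit.P0, atol=1e-10)
        np.testing.assert_allclose(fit.P0, fit.P0.T, atol=1e-12)

    def test_binary_weighted_residual_orthogonal_to_weighted_design(self, rng):
        n = 120
        X = _design(n, rng)
        G = rng.standard_normal((n, 1))
        lp = X @ [0.1, 0.5, -0.4] + 0.5 * G[:, 0]
        y = rng.binomial(1, 1 / (1 + np.exp(-lp))).astype(float)
        fit = fit_null_h0prime(X, G, y, "binary")
        mu = fit.mu_hat
        Zd = fit.Z * np.sqrt(mu * (1 - mu))[:, None]
        # IRLS stationarity: the weighted working residual is orthogonal to Zdag
        assert np.abs(Zd.T @ fit.resid).max() < 1e-6

    def test_no_features_reduces_to_confounder_design(self, rng):
        n = 50
        X = _design(n, rng)
        y = rng.standard_normal(n)
        fit = fit_null_h0prime(X, None, y, "continuous")
        assert fit.dim_d == X.shape[1]
        assert fit.Z.shape == (n, 3)

    def test_n_not_exceeding_d_errors(self, rng):
        X = np.column_stack([np.ones(3), rng.standard_normal(3)])
        with pytest.raises(ModelFitError):
            fit_null_h0prime(X, np.eye(3)[:, :1], rng.standard_normal(3), "continuous")


class TestScoreRandom:
    @pytest.mark.parametrize("trait", ["continuous", "binary"])
    def test_identity_kernel_is_exactly_null(self, trait, rng):
        n = 70
        X = _design(n, rng)
        if trait == "continuous":
            y = X @ [0.1, 0.5, -0.4] + rng.standard_normal(n)
        else:
            y = rng.binomial(1, 1 / (1 + np.exp(-X @ [0.1, 0.5, -0.4]))).astype(float)
        fit = fit_null_h0prime(X, None, y, trait)
        Q, p = score_random(fit, np.eye(n))
        assert Q == 0.0
        assert p == 0.5

    def test_trait_type_mismatch_rejected(self, rng):
        n = 40
        X = _design(n, rng)
        y = rng.standard_normal(n)
        fit = fit_null_h0prime(X, None, y, "continuous")
        with pytest.raises(ValueError):
            score_random_binary(fit, np.eye(n))

    def test_relabeling_subjects_leaves_statistic_unchanged(self, rng):
        n = 80
        X = _design(n, rng)
        S = _psd_kernel(n, rng)
        y = rng.binomial(1, 1 / (1 + np.exp(-X @ [0.1, 0.5, -0.4]))).astype(float)
        fit = fit_null_h0prime(X, None, y, "binary")
        Q, _ = score_random_binary(fit, S)
        perm = rng.permutation(n)
        fit_p = fit_null_h0prime(X[perm], None, y[perm], "binary")
        Q_p, _ = score_random_binary(fit_p, S[np.ix_(perm, perm)])
        assert Q_p == pytest.approx(Q, abs=1e-10)

    def test_two_sided_option_doubles_the_upper_tail(self, rng):
        n = 60
        X = _design(n, rng)
        S = _psd_kernel(n, rng)
        y = X @ [0.1, 0.5, -0.4] + rng.standard_normal(n)
        fit = fit_null_h0prime(X, None, y, "continuous")
        Q, p1 = score_random_continuous(fit, S)
        _, p2 = score_random_continuous(fit, S, two_sided=True)
        assert p2 == pytest.approx(2 * min(p1, 1 - p1), rel=1e-12)

    def test_null_statistic_is_approximately_standard_normal(self, rng):
        # moderate-n sanity check of the asymptotic null law
        n, reps = 150, 400
        X = _design(n, rng)
        S = _psd_kernel(n, rng)
        qs = []
        for _ in range(reps):
            y = X @ [0.1, 0.5, -0.4] + rng.standard_normal(n)
            fit = fit_null_h0prime(X, None, y, "continuous")
            Q, _ = score_random_continuous(fit, S)
            qs.append(Q)
        qs = np.asarray(qs)
        assert abs(qs.mean()) < 3 / math.sqrt(reps) + 0.1
        assert 0.7 < qs.var() < 1.4


class TestFisherCombine:
    def test_both_ones_give_null_combination(self):
        stat, p = fisher_combine(1.0, 1.0)
        assert stat == 0.0 and p == 1.0

    def test_exp_minus_one_inputs_match_chi2_closed_form(self):
        stat, p = fisher_combine(math.exp(-1), math.exp(-1))
        assert stat == pytest.approx(4.0)
        # chi^2_4 survival: (1 + x/2) exp(-x/2)
        assert p == pytest.approx(3 * math.exp(-2), rel=1e-12)

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            stat, p = fisher_combine(0.0, 0.5)
        assert np.isfinite(stat) and 0 < p < 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine(1.5, 0.5)


@pytest.fixture(scope="module")
def aligned_inputs(small_cohort):
    rng = np.random.default_rng(99)
    n = small_cohort.n
    ids = small_cohort.subject_ids
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    cov = CovariateTable(X=X, subject_ids=list(ids))
    y = rng.standard_normal(n)
    phe = PhenotypeVector(y=y, trait_type="continuous", subject_ids=list(ids))
    kernel = psd_project(build_kernel(small_cohort, SubstitutionScheme()))
    return small_cohort, cov, phe, kernel


class TestTcrlTest:
    def test_combined_equals_fisher_of_components(self, aligned_inputs):
        rs, cov, phe, kernel = aligned_inputs
        res = tcrl_test(rs, cov, phe, mode="combined", kernel=kernel)
        fixed = tcrl_test(rs, cov, phe, mode="fixed")
        assert res.p_eta == pytest.approx(fixed.p_eta)
        _, p_comb = fisher_combine(res.p_eta, res.p_tau2)
        assert res.p_combined == pytest.approx(p_comb)
        assert res.p_value == res.p_combined
        assert res.fisher_stat >= 0

    def test_random_mode_uses_confounder_only_design(self, aligned_inputs):
        rs, cov, phe, kernel = aligned_inputs
        res = tcrl_test(rs, cov, phe, mode="random", kernel=kernel)
        assert res.diagnostics["dim_d"] == cov.X.shape[1]
        assert res.p_eta is None
        assert res.p_value == res.p_tau2

    def test_combined_mode_includes_features_in_null_design(self, aligned_inputs):
        rs, cov, phe, kernel = aligned_inputs
        res = tcrl_test(rs, cov, phe, mode="combined", kernel=kernel)
        assert res.diagnostics["dim_d"] == cov.X.shape[1] + 1
        assert res.scheme == "BLOSUM62"

    def test_misordered_subjects_rejected(self, aligned_inputs):
        rs, cov, phe, kernel = aligned_inputs
        shuffled = CovariateTable(
            X=cov.X[::-1], subject_ids=list(reversed(cov.subject_ids)),
        )
        with pytest.raises(ValueError, match="order"):
            tcrl_test(rs, shuffled, phe, kernel=kernel)

    def test_unknown_mode_rejected(self, aligned_inputs):
        rs, cov, phe, kernel = aligned_inputs
        with pytest.raises(ValueError):
            tcrl_test(rs, cov, phe, mode="everything")
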
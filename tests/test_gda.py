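"""Gaussian discriminant fits, posteriors, and the two operating-curve sweeps."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from dermeval.cohort import FeatureTable
from dermeval.gda import (
    VARIANTS,
    GaussianClassModel,
    fit_gda,
    posterior,
    prior_sweep,
    score_cohort,
    threshold_sweep,
)
from dermeval.metrics import auc_roc
from dermeval.simulate import CohortSpec, simulate_feature_table


def _model_1d(mu0=-1.0, mu1=1.0, var=1.0, prior=0.5):
    return GaussianClassModel(
        "lda",
        np.array([mu0]),
        np.array([mu1]),
        np.array([[var]]),
        np.array([[var]]),
        prior,
        0.0,
    )


def _random_table(rng, n_lo=10, n_hi=30, d_max=3) -> FeatureTable:
    n = int(rng.integers(n_lo, n_hi))
    d = int(rng.integers(1, d_max + 1))
    X = rng.standard_normal((n, d))
    labels = np.r_[np.ones(2, dtype=int), np.zeros(2, dtype=int),
                   rng.integers(0, 2, n - 4)]
    return FeatureTable(X, labels)


class TestFit:
    def test_1d_lda_hand_computation(self):
        # class 0: {-1, 1}; class 1: {1, 3} -> means 0 and 2, pooled var 2
        ft = FeatureTable(np.array([[-1.0], [1.0], [1.0], [3.0]]), [0, 0, 1, 1])
        m = fit_gda(ft, "lda", ridge=0.0)
        assert m.mu0[0] == 0.0 and m.mu1[0] == 2.0
        assert m.cov0[0, 0] == pytest.approx(2.0)
        assert m.prior1 == 0.5

    def test_dqda_equals_qda_with_zeroed_off_diagonals(self):
        rng = np.random.default_rng(5)
        ft = _random_table(rng, 30, 40, 3)
        qda = fit_gda(ft, "qda", ridge=1e-9)
        dqda = fit_gda(ft, "dqda", ridge=1e-9)
        assert np.allclose(np.diag(np.diag(qda.cov0)), dqda.cov0)
        assert np.allclose(np.diag(np.diag(qda.cov1)), dqda.cov1)

    def test_parameter_recovery_large_n(self):
        cohort = CohortSpec(n_test=20000, n_melanoma=10000, seed=9)
        mu0, mu1 = np.array([0.0, 1.0]), np.array([1.5, -0.5])
        ft = simulate_feature_table(cohort, 2, mu0, mu1, np.eye(2), np.eye(2))
        m = fit_gda(ft, "qda")
        assert np.allclose(m.mu0, mu0, atol=0.05)
        assert np.allclose(m.mu1, mu1, atol=0.05)
        assert np.allclose(m.cov0, np.eye(2), atol=0.06)

    def test_one_class_table_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(np.zeros((4, 1)), [1, 1, 1, 1])

    def test_too_few_rows_per_class_rejected(self):
        ft = FeatureTable(np.arange(3.0).reshape(-1, 1), [0, 0, 1])
        with pytest.raises(ValueError):
            fit_gda(ft, "lda")

    def test_singular_covariance_without_ridge_names_variant(self):
        # two identical rows per class -> zero within-class variance
        X = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0], [2.0, 2.0]])
        ft = FeatureTable(X, [0, 0, 1, 1])
        with pytest.raises(np.linalg.LinAlgError, match="qda"):
            fit_gda(ft, "qda", ridge=0.0)
        fit_gda(ft, "qda", ridge=1e-3)  # ridge rescues the fit

    def test_empirical_prior_is_class_fraction(self):
        ft = FeatureTable(np.arange(10.0).reshape(-1, 1), [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert fit_gda(ft, "lda").prior1 == pytest.approx(0.3)


class TestPosterior:
    def test_midpoint_is_half(self):
        post, _ = posterior(_model_1d(), [[0.0]])
        assert post[0] == pytest.approx(0.5)

    def test_closed_form_log_odds(self):
        # log-odds at x: (mu1-mu0)x/var - (mu1^2-mu0^2)/(2 var) = 2x for this model
        post, _ = posterior(_model_1d(), [[1.0]])
        assert post[0] == pytest.approx(expit(2.0), abs=1e-12)

    def test_prior_dominance_monotone(self):
        model = _model_1d()
        priors = [0.01, 0.2, 0.5, 0.9, 0.999, 0.9999999]
        posts = [posterior(model, [[0.3]], p)[0][0] for p in priors]
        assert all(a < b for a, b in zip(posts, posts[1:]))
        assert posts[-1] > 0.999

    def test_saturation_flagged_at_extreme_log_odds(self):
        model = _model_1d(var=0.001)
        post, sat = posterior(model, [[5.0]])
        assert post[0] == 1.0 and bool(sat[0])

    def test_same_side_saturation_non_increasing_toward_balanced_prior(self):
        """Raising a tiny prior toward 1/2 monotonically raises every posterior,
        so the count saturated at 0 shrinks; symmetrically for saturation at 1
        as an extreme-high prior falls toward 1/2. (A lesion whose class
        log-density difference alone exceeds the saturation range can
        re-saturate on the opposite side, so only the same-side count is
        monotone.)"""
        model = _model_1d(var=0.01)
        X = np.linspace(-3, 3, 41).reshape(-1, 1)
        eps = 1e-15
        sat0 = [
            int((posterior(model, X, p)[0] <= eps).sum())
            for p in (1e-12, 1e-6, 1e-3, 0.5)
        ]
        assert all(a >= b for a, b in zip(sat0, sat0[1:]))
        sat1 = [
            int((posterior(model, X, p)[0] >= 1 - eps).sum())
            for p in (1 - 1e-12, 1 - 1e-6, 1 - 1e-3, 0.5)
        ]
        assert all(a >= b for a, b in zip(sat1, sat1[1:]))

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            posterior(_model_1d(), [[np.nan]])

    def test_refit_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(17)
        ft = _random_table(rng, 40, 50, 2)
        scale, shift = np.array([3.0, 0.25]), np.array([-7.0, 2.0])
        ft2 = FeatureTable(ft.X * scale + shift, ft.labels)
        for variant in VARIANTS:
            m1 = fit_gda(ft, variant, ridge=0.0)
            m2 = fit_gda(ft2, variant, ridge=0.0)
            p1, _ = posterior(m1, ft.X)
            p2, _ = posterior(m2, ft2.X)
            assert np.allclose(p1, p2, atol=1e-9)


class TestSweeps:
    def test_threshold_sweep_separates_well_separated_classes(self):
        cohort = CohortSpec(n_test=400, n_melanoma=100, seed=3)
        ft = simulate_feature_table(cohort, 2, [0, 0], [3, 3], np.eye(2), np.eye(2))
        model = fit_gda(ft, "lda")
        assert auc_roc(threshold_sweep(model, ft)) > 0.95

    def test_sweep_point_count_bounded(self):
        rng = np.random.default_rng(29)
        ft = _random_table(rng, 15, 25, 2)
        model = fit_gda(ft, "lda")
        curve = threshold_sweep(model, ft)
        assert len(curve.fpr) <= ft.n + 1

    def test_prior_extremes_reach_corners(self):
        rng = np.random.default_rng(31)
        ft = _random_table(rng, 12, 20, 2)
        model = fit_gda(ft, "qda")
        curve = prior_sweep(model, ft)
        pts = curve.points()
        assert (0.0, 0.0) in pts and (1.0, 1.0) in pts

    def test_invalid_grid_rejected(self):
        rng = np.random.default_rng(37)
        ft = _random_table(rng)
        model = fit_gda(ft, "lda")
        with pytest.raises(ValueError):
            prior_sweep(model, ft, grid=[0.0, 0.5])
        with pytest.raises(ValueError):
            prior_sweep(model, ft, grid=[0.5, 0.2])

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_prior_and_threshold_sweeps_identical(self, variant):
        """Varying the prior shifts every log-odds by a constant, so the
        operating-point sets of the two sweeps coincide exactly."""
        rng = np.random.default_rng(43)
        for _ in range(25):
            ft = _random_table(rng)
            model = fit_gda(ft, variant)
            c1 = threshold_sweep(model, ft)
            s1 = set(zip(c1.fpr.tolist(), c1.tpr.tolist()))
            c2 = prior_sweep(model, ft)
            s2 = set(zip(c2.fpr.tolist(), c2.tpr.tolist()))
            assert s1 == s2

    def test_qda_with_equal_covariances_matches_lda(self):
        rng = np.random.default_rng(47)
        ft = _random_table(rng, 40, 60, 2)
        lda = fit_gda(ft, "lda", ridge=0.0)
        forced = GaussianClassModel(
            "qda", lda.mu0, lda.mu1, lda.cov0, lda.cov1, lda.prior1, 0.0
        )
        p1, _ = posterior(lda, ft.X)
        p2, _ = posterior(forced, ft.X)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_dlda_converges_to_lda_on_diagonal_population(self):
        cohort = CohortSpec(n_test=8000, n_melanoma=2000, seed=13)
        ft = simulate_feature_table(
            cohort, 2, [0, 0], [1, 1], np.diag([1.0, 2.0]), np.diag([1.0, 2.0])
        )
        p_lda, _ = posterior(fit_gda(ft, "lda"), ft.X)
        p_dlda, _ = posterior(fit_gda(ft, "dlda"), ft.X)
        assert np.allclose(p_lda, p_dlda, atol=0.02)

    def test_score_cohort_flags_degenerate_training(self):
        # near-point classes saturate the posteriors of distant lesions
        X = np.array([[0.0], [1e-6], [10.0], [10.0 + 1e-6]])
        ft = FeatureTable(X, [0, 0, 1, 1])
        model = fit_gda(ft, "lda")
        cohort = score_cohort(model, ft)
        assert ((cohort.scores == 0.0) | (cohort.scores == 1.0)).any()
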
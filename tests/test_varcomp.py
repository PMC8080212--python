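import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from devgen.pedigree import kinship_from_pedigree
from devgen.simulate import (SimConfig, TraitParams, gxage_covariance,
                             sim_bivariate, sim_pedigrees,
                             sim_phenotype_gxage)
from devgen.varcomp import (BivariateModel, GxAgeModel, InverseNormalTransformer,
                            PolygenicModel, bh_fdr, fit_gxage, fit_polygenic,
                            inverse_normal, lrt_nested, variance_by_age)


class TestInverseNormal:
    def test_three_values(self):
        out = inverse_normal([5.0, 1.0, 3.0])
        assert out[2] == pytest.approx(0.0, abs=1e-12)
        expected = norm.ppf(2.625 / 3.25)
        assert out[0] == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.870, abs=1e-3)
        assert out[1] == pytest.approx(-expected)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = inverse_normal(rng.exponential(size=1000))
        assert abs(out.mean()) < 0.01
        assert abs(out.std() - 1.0) < 0.02

    def test_ties_and_missing_preserved(self):
        out = inverse_normal([1.0, 1.0, 2.0, np.nan, 3.0])
        assert np.isnan(out[3])
        assert out[0] == out[1]

    def test_errors(self):
        with pytest.raises(ValueError, match="identical"):
            inverse_normal([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="at least 3"):
            inverse_normal([1.0, 2.0])

    def test_transformer(self):
        rng = np.random.default_rng(1)
        X = rng.exponential(size=(100, 3))
        out = InverseNormalTransformer().fit_transform(X)
        assert out.shape == (100, 3)
        assert np.abs(out.mean(axis=0)).max() < 0.05


class TestBhFdr:
    def test_hand_enumerated_example(self):
        reject, p_adj = bh_fdr([0.001, 0.01, 0.02, 0.04, 0.5], q=0.05)
        assert list(reject) == [True, True, True, True, False]

    def test_no_rejections_at_unit_pvalues(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_test_reduces_to_nominal(self):
        reject, p_adj = bh_fdr([0.04], q=0.05)
        assert reject[0]
        assert p_adj[0] == pytest.approx(0.04)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestLrt:
    def test_zero_statistic(self):
        assert lrt_nested(-10.0, -10.0, boundary=True).p_value == 0.5
        assert lrt_nested(-10.0, -10.0, boundary=False).p_value == 1.0

    def test_boundary_mixture_quantile(self):
        res = lrt_nested(0.0, -2.706 / 2, boundary=True)
        assert res.statistic == pytest.approx(2.706)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_interior_chi2_quantile(self):
        res = lrt_nested(0.0, -3.841 / 2, boundary=False)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_full_below_null_raises(self):
        with pytest.raises(ValueError, match="refit"):
            lrt_nested(-11.0, -10.0)


class TestPolygenicOracle:
    def test_loglik_matches_dense_mvn(self, toy_varcomp):
        """Implementation log-likelihood equals a from-scratch dense MVN
        density on the N = 6 toy."""
        y, K, ages, X = toy_varcomp
        m = PolygenicModel().fit(y, K, X)
        omega = m.sigma2_g_ * K + m.sigma2_e_ * np.eye(6)
        ll = multivariate_normal(X @ m.beta_, omega).logpdf(y)
        assert m.loglik_ == pytest.approx(ll, abs=1e-8)

    def test_variance_decomposition_identity(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        m = PolygenicModel().fit(y, K, X)
        assert m.sigma2_g_ + m.sigma2_e_ == pytest.approx(m.sigma2_p_, abs=1e-10)
        assert m.h2_ * m.sigma2_p_ == pytest.approx(m.sigma2_g_, abs=1e-10)

    def test_affine_invariance_of_h2(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        h2a = PolygenicModel().fit(y, K, X).h2_
        h2b = PolygenicModel().fit(3.5 * y - 2.0, K, X).h2_
        assert h2a == pytest.approx(h2b, abs=1e-6)

    def test_permutation_invariance(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        perm = np.array([3, 0, 5, 1, 4, 2])
        h2a = PolygenicModel().fit(y, K, X).h2_
        h2b = PolygenicModel().fit(y[perm], K[np.ix_(perm, perm)], X[perm]).h2_
        assert h2a == pytest.approx(h2b, abs=1e-6)

    def test_missing_rows_dropped(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        y2 = y.copy()
        y2[3] = np.nan
        m = PolygenicModel().fit(y2, K, X)
        assert m.n_ == 5

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            PolygenicModel().fit(np.zeros(3), np.eye(3),
                                 np.column_stack([np.ones(3), np.arange(3)]))

    def test_reml_option(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        m = PolygenicModel(method="reml").fit(y, K, X)
        assert np.isfinite(m.loglik_)
        with pytest.raises(ValueError, match="method"):
            PolygenicModel(method="bogus").fit(y, K, X)


class TestPolygenicRecovery:
    def test_sib_cohort_recovery(self, sib_quad_cohort):
        """Mean h2-hat near 0.5 on sib-pair cohorts (quick 6-replicate
        version of the full recovery study)."""
        ped, K = sib_quad_cohort
        truth = TraitParams(0.5, 0.5, 0.0, 0.0, 0.0)
        ests = [PolygenicModel().fit(
            sim_phenotype_gxage(K, ped.ages, truth, seed=100 + s), K).h2_
            for s in range(6)]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.07)

    def test_estimator_spread_shrinks_with_n(self):
        """Estimates concentrate as the cohort grows (consistency)."""
        truth = TraitParams(0.5, 0.5, 0.0, 0.0, 0.0)
        spread = {}
        for n_fam in (125, 500):
            cfg = SimConfig(n_families=n_fam, children_per_family=2,
                            n_singletons=0)
            ped = sim_pedigrees(cfg, seed=n_fam)
            K, _ = kinship_from_pedigree(ped)
            ests = [PolygenicModel().fit(
                sim_phenotype_gxage(K, ped.ages, truth, seed=s), K).h2_
                for s in range(8)]
            spread[n_fam] = np.sqrt(np.mean((np.array(ests) - 0.5) ** 2))
        assert spread[500] < spread[125]

    def test_null_trait_estimates_near_zero(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        rng = np.random.default_rng(5)
        ests = [PolygenicModel().fit(rng.standard_normal(len(ped)), K).h2_
                for _ in range(10)]
        assert np.mean(ests) < 0.05


class TestGxAge:
    def test_loglik_matches_dense_mvn(self, toy_varcomp):
        """Omega assembled entrywise and the dense MVN density agree with
        the blockwise implementation on the N = 6 toy."""
        y, K, ages, X = toy_varcomp
        m = GxAgeModel(n_starts=1, compute_lrts=False, compute_se=False).fit(
            y, K, ages, X)
        params = TraitParams(m.sigma2_g0_, m.sigma2_e0_, m.gamma_g_,
                             m.gamma_e_, m.lambda_, ref_age=m.ref_age_)
        omega = gxage_covariance(K, ages, params)
        ll = multivariate_normal(X @ m.beta_, omega).logpdf(y)
        assert m.loglik_ == pytest.approx(ll, abs=1e-8)

    def test_reduces_to_polygenic_when_constrained(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        y = sim_phenotype_gxage(K, ped.ages, TraitParams(0.5, 0.5, 0, 0, 0),
                                seed=3)
        poly = PolygenicModel().fit(y, K)
        gx = GxAgeModel(n_starts=2, compute_lrts=False, compute_se=False).fit(
            y, K, ped.ages, fix={"gamma_g": 0.0, "gamma_e": 0.0, "lambda": 0.0})
        assert gx.loglik_ == pytest.approx(poly.loglik_, abs=1e-6)

    def test_full_likelihood_at_least_null(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        y = sim_phenotype_gxage(K, ped.ages,
                                TraitParams(0.5, 0.5, -0.1, 0.05, 0.0), seed=4)
        m = GxAgeModel(n_starts=2, seed=1, compute_se=False).fit(y, K, ped.ages)
        for lrt in (m.lrt_gamma_g_, m.lrt_gamma_e_, m.lrt_lambda_):
            assert lrt.statistic >= 0

    def test_gamma_sign_recovery(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        truth = TraitParams(0.5, 0.5, -0.15, 0.06, 0.0)
        gs = [fit_gxage(sim_phenotype_gxage(K, ped.ages, truth, seed=40 + s),
                        K, ped.ages, n_starts=1, compute_lrts=False,
                        compute_se=False).gamma_g_
              for s in range(5)]
        assert np.mean(gs) == pytest.approx(-0.15, abs=0.08)
        assert (np.array(gs) < 0).sum() >= 4

    def test_standard_errors_finite(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        y = sim_phenotype_gxage(K, ped.ages,
                                TraitParams(0.5, 0.5, -0.1, 0.05, 0.1), seed=6)
        m = GxAgeModel(n_starts=1, compute_lrts=False).fit(y, K, ped.ages)
        assert np.isfinite(m.se_["gamma_g"])
        assert np.isfinite(m.se_["gamma_e"])


class TestVarianceByAge:
    def _fit_like(self, ag, gg, ae, ge):
        m = GxAgeModel()
        m.alpha_g_, m.gamma_g_, m.alpha_e_, m.gamma_e_ = ag, gg, ae, ge
        m.lambda_, m.ref_age_ = 0.0, 14.5
        return m

    def test_flat_curves_without_interaction(self):
        tab = variance_by_age(self._fit_like(np.log(0.4), 0.0, np.log(0.6), 0.0),
                              np.linspace(8, 21, 14))
        assert tab["sigma2_g"].std() < 1e-12
        assert tab["h2"].std() < 1e-12

    def test_variance_ratio_across_age_span(self):
        """gamma_g = -0.146 halves-and-more genetic variance across 13 years:
        ratio exp(-0.146 * 13) ~ 0.150."""
        tab = variance_by_age(self._fit_like(np.log(0.4), -0.146, np.log(0.6), 0.0),
                              np.array([8.0, 21.0]))
        ratio = tab["sigma2_g"].iloc[1] / tab["sigma2_g"].iloc[0]
        assert ratio == pytest.approx(np.exp(-0.146 * 13), rel=1e-9)
        assert ratio == pytest.approx(0.150, abs=0.001)

    def test_h2_identity_pointwise(self):
        tab = variance_by_age(self._fit_like(-0.7, -0.1, -0.4, 0.05),
                              np.linspace(8, 21, 27))
        np.testing.assert_allclose(
            tab["h2"], tab["sigma2_g"] / (tab["sigma2_g"] + tab["sigma2_e"]),
            atol=1e-12)


class TestBivariate:
    def test_loglik_matches_dense_mvn(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        rng = np.random.default_rng(2)
        y2 = rng.standard_normal(6)
        m = BivariateModel(n_starts=1, compute_lrts=False,
                           compute_se=False).fit(y, y2, K, X)
        I6 = np.eye(6)
        cg = m.rho_g_ * np.sqrt(m.sigma2_g_[0] * m.sigma2_g_[1])
        ce = m.rho_e_ * np.sqrt(m.sigma2_e_[0] * m.sigma2_e_[1])
        omega = np.block([
            [m.sigma2_g_[0] * K + m.sigma2_e_[0] * I6, cg * K + ce * I6],
            [cg * K + ce * I6, m.sigma2_g_[1] * K + m.sigma2_e_[1] * I6]])
        p = X.shape[1]
        mu = np.concatenate([X @ m.beta_[:p], X @ m.beta_[p:]])
        ll = multivariate_normal(mu, omega).logpdf(np.concatenate([y, y2]))
        assert m.loglik_ == pytest.approx(ll, abs=1e-8)

    def test_rho_p_decomposition_identity(self, toy_varcomp):
        y, K, _, X = toy_varcomp
        rng = np.random.default_rng(3)
        m = BivariateModel(n_starts=1, compute_lrts=False,
                           compute_se=False).fit(y, rng.standard_normal(6), K, X)
        expected = (m.rho_g_ * np.sqrt(m.h2_[0] * m.h2_[1])
                    + m.rho_e_ * np.sqrt((1 - m.h2_[0]) * (1 - m.h2_[1])))
        assert m.rho_p_ == pytest.approx(expected, abs=1e-8)

    def test_null_recovery(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        y1, y2 = sim_bivariate(K, {"h2_1": 0.5, "h2_2": 0.5,
                                   "rho_g": 0.0, "rho_e": 0.0}, seed=8)
        m = BivariateModel(n_starts=1, compute_lrts=False,
                           compute_se=False).fit(y1, y2, K)
        assert abs(m.rho_g_) < 0.15
        assert abs(m.rho_e_) < 0.1

    def test_negative_rho_g_recovery(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        ests = []
        for s in range(4):
            y1, y2 = sim_bivariate(K, {"h2_1": 0.5, "h2_2": 0.5,
                                       "rho_g": -0.4, "rho_e": 0.0},
                                   seed=60 + s)
            ests.append(BivariateModel(n_starts=1, compute_lrts=False,
                                       compute_se=False).fit(y1, y2, K).rho_g_)
        assert np.mean(ests) == pytest.approx(-0.4, abs=0.12)

    def test_missing_one_trait_uses_observed_rows(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        sub = np.arange(400)
        Ks = K[np.ix_(sub, sub)]
        y1, y2 = sim_bivariate(Ks, {"h2_1": 0.5, "h2_2": 0.5,
                                    "rho_g": -0.4, "rho_e": 0.0}, seed=9)
        y1m = y1.copy()
        y1m[::10] = np.nan
        m = BivariateModel(n_starts=1, compute_lrts=False,
                           compute_se=False).fit(y1m, y2, Ks)
        assert m.n_ == 400  # rows with either trait observed are retained
        assert np.isfinite(m.loglik_)

    def test_lrt_pvalues_present(self, sib_quad_cohort):
        ped, K = sib_quad_cohort
        sub = np.arange(600)
        Ks = K[np.ix_(sub, sub)]
        y1, y2 = sim_bivariate(Ks, {"h2_1": 0.5, "h2_2": 0.5,
                                    "rho_g": -0.5, "rho_e": 0.0}, seed=10)
        m = BivariateModel(n_starts=1, compute_se=False).fit(y1, y2, Ks)
        assert 0 <= m.lrt_rho_g_.p_value <= 1
        assert 0 <= m.lrt_rho_e_.p_value <= 1
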
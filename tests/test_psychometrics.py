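import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import norm

from devgen.psychometrics import (BifactorEstimator, BifactorModel, bvn_cdf,
                                  build_bifactor_truth, default_item_pattern,
                                  fit_bifactor, fit_hierarchical, score_map,
                                  tetrachoric, tetrachoric_matrix)
from devgen.simulate import sim_items


def _bvn_cdf_quadrature(h, k, rho):
    """Independent oracle: direct 2-D integration of the BVN density."""
    def dens(y, x):
        z = (x * x - 2 * rho * x * y + y * y) / (1 - rho * rho)
        return np.exp(-z / 2) / (2 * np.pi * np.sqrt(1 - rho * rho))

    val, _ = integrate.dblquad(dens, -8.0, h, -8.0, k, epsabs=1e-10)
    return val


def _tetrachoric_oracle(n00, n01, n10, n11):
    """ML tetrachoric via the quadrature CDF (independent of owens_t)."""
    n = n00 + n01 + n10 + n11
    h = norm.ppf(1 - (n10 + n11) / n)
    k = norm.ppf(1 - (n01 + n11) / n)
    grid = np.linspace(-0.98, 0.98, 197)
    best, best_ll = 0.0, -np.inf
    for r in grid:
        phk = _bvn_cdf_quadrature(h, k, r)
        p = np.clip([phk, norm.cdf(h) - phk, norm.cdf(k) - phk,
                     1 - norm.cdf(h) - norm.cdf(k) + phk], 1e-12, 1)
        ll = n00 * np.log(p[0]) + n01 * np.log(p[1]) + \
            n10 * np.log(p[2]) + n11 * np.log(p[3])
        if ll > best_ll:
            best, best_ll = r, ll
    return best


class TestBvnCdf:
    @pytest.mark.parametrize("h,k,rho", [
        (0.5, -0.3, 0.4), (-1.2, 0.8, -0.6), (0.0, 0.7, 0.3),
        (0.0, 0.0, 0.5), (1.5, 1.5, 0.9), (-0.4, -0.4, -0.9),
    ])
    def test_against_quadrature(self, h, k, rho):
        assert bvn_cdf(h, k, rho) == pytest.approx(
            _bvn_cdf_quadrature(h, k, rho), abs=1e-7)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.3, 0.8, 1.0) == pytest.approx(norm.cdf(0.3))
        assert bvn_cdf(0.3, 0.8, -1.0) == pytest.approx(
            norm.cdf(0.3) + norm.cdf(0.8) - 1)


class TestTetrachoric:
    def test_item_with_exact_copy(self):
        assert tetrachoric(40, 0, 0, 60) == 1.0
        assert tetrachoric(0, 30, 70, 0) == -1.0

    @staticmethod
    def _cells(a, b):
        a, b = a.astype(bool), b.astype(bool)
        return (int((~a & ~b).sum()), int((~a & b).sum()),
                int((a & ~b).sum()), int((a & b).sum()))

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.standard_normal(5000) > 0).astype(int)
        b = (rng.standard_normal(5000) > 0.5).astype(int)
        assert abs(tetrachoric(*self._cells(a, b))) < 0.05

    def test_latent_rho_half_recovered(self):
        """Items dichotomized at 0 from latent rho = 0.5, n = 10,000."""
        rng = np.random.default_rng(1)
        L = np.linalg.cholesky([[1, 0.5], [0.5, 1]])
        z = rng.standard_normal((10000, 2)) @ L.T
        a, b = (z[:, 0] > 0).astype(int), (z[:, 1] > 0).astype(int)
        est = tetrachoric(*self._cells(a, b))
        assert est == pytest.approx(0.5, abs=0.03)

    def test_matches_quadrature_ml_oracle(self):
        """Estimator agrees with a from-scratch quadrature ML on tabled
        counts (to the oracle's own grid resolution)."""
        for counts in [(400, 100, 120, 380), (300, 200, 150, 350)]:
            est = tetrachoric(*counts)
            oracle = _tetrachoric_oracle(*counts)
            assert abs(est - oracle) <= 0.01 + 1e-9

    def test_matrix_shape_and_unusable_items(self):
        rng = np.random.default_rng(2)
        items = pd.DataFrame({
            "a": rng.integers(0, 2, 200),
            "b": rng.integers(0, 2, 200),
            "all_one": np.ones(200, dtype=int),
        })
        R = tetrachoric_matrix(items)
        assert R.shape == (3, 3)
        assert np.isnan(R.loc["a", "all_one"])
        assert R.loc["a", "a"] == 1.0


@pytest.fixture(scope="module")
def bifactor_recovery():
    """Items from a known bifactor truth (24 items, general 0.6,
    specific 0.4, n = 4,000) plus the fitted model."""
    pattern = default_item_pattern(24)
    truth = build_bifactor_truth(pattern, 0.6, 0.4,
                                 {d: 0.2 for d in set(pattern)})
    rng = np.random.default_rng(7)
    eta = rng.standard_normal((4000, 5))
    items = sim_items(eta, truth, seed=8)
    R = tetrachoric_matrix(items)
    model = fit_bifactor(R, pattern, items.mean(), n_starts=3, seed=0)
    return pattern, truth, eta, items, R, model


class TestBifactorFit:
    def test_loading_recovery(self, bifactor_recovery):
        pattern, truth, _, _, _, model = bifactor_recovery
        free = truth.loadings.to_numpy() != 0
        err = (model.loadings.to_numpy() - truth.loadings.to_numpy())[free]
        assert np.sqrt((err**2).mean()) < 0.08

    def test_implied_matrix_reproduces_tetrachorics(self, bifactor_recovery):
        *_, R, model = bifactor_recovery
        E = R.to_numpy() - model.implied_corr()
        off = ~np.eye(len(E), dtype=bool)
        assert np.sqrt((E[off] ** 2).mean()) < 0.05

    def test_discrepancy_not_worse_than_truth(self, bifactor_recovery):
        pattern, truth, _, _, R, model = bifactor_recovery
        E_true = R.to_numpy() - truth.implied_corr()
        np.fill_diagonal(E_true, 0.0)
        assert model.discrepancy <= 0.5 * (E_true**2).sum() + 1e-9

    def test_pure_general_data_gives_null_specifics(self):
        pattern = default_item_pattern(24)
        truth = build_bifactor_truth(pattern, 0.6, 0.0,
                                     {d: 0.25 for d in set(pattern)})
        rng = np.random.default_rng(3)
        items = sim_items(rng.standard_normal((4000, 5)), truth, seed=4)
        model = fit_bifactor(tetrachoric_matrix(items), pattern, items.mean(),
                             n_starts=3, seed=0)
        doms = [c for c in model.loadings.columns if c != "general"]
        spec = np.abs(model.loadings[doms].to_numpy())
        # specific loadings soak up tetrachoric sampling noise up to the
        # rank-1 noise-block scale (~0.15 mean at n = 4,000, 6 items/domain);
        # the test pins them to that noise level and requires the general
        # factor itself to be cleanly recovered
        assert spec[spec > 0].mean() < 0.2
        assert np.abs(model.loadings["general"].to_numpy() - 0.6).max() < 0.1
        # specifics explain far less variance than the general factor
        assert (spec**2).sum() < 0.2 * (model.loadings["general"] ** 2).sum()

    def test_thresholds_from_endorsement(self, bifactor_recovery):
        _, _, _, items, R, model = bifactor_recovery
        np.testing.assert_allclose(
            model.thresholds, norm.ppf(1 - items.mean().to_numpy()))

    def test_pattern_needs_three_items_per_domain(self):
        pattern = pd.Series(["a", "a", "b"], index=["i1", "i2", "i3"])
        with pytest.raises(ValueError, match=">= 3 items"):
            fit_bifactor(np.eye(3), pattern, pd.Series([0.2, 0.2, 0.2],
                                                       index=pattern.index))


class TestHierarchicalFit:
    def test_second_order_recovery(self):
        """Second-order loadings (0.7, 0.6, 0.5, 0.4) recovered within 0.1."""
        pattern = default_item_pattern(24)
        doms = ["anxious_misery", "externalizing", "fear", "psychosis"]
        so_truth = dict(zip(doms, [0.7, 0.6, 0.5, 0.4]))
        lam = pd.DataFrame(0.0, index=pattern.index, columns=doms + ["general"])
        for d in doms:
            lam.loc[pattern == d, d] = 0.7
        truth = BifactorModel(lam, np.zeros(24), "hierarchical",
                              second_order=so_truth, item_domains=pattern)
        rng = np.random.default_rng(5)
        eta = rng.standard_normal((4000, 5))
        items = sim_items(eta, truth, seed=6)
        model = fit_hierarchical(tetrachoric_matrix(items), pattern,
                                 items.mean(), n_starts=3, seed=0)
        for d in doms:
            assert model.second_order[d] == pytest.approx(so_truth[d], abs=0.1)
        # implied factor correlation is the outer product of 2nd-order loadings
        est = model.second_order
        assert est["anxious_misery"] * est["externalizing"] == pytest.approx(
            0.7 * 0.6, abs=0.12)

    def test_unit_second_order_collapses_to_one_factor(self):
        pattern = default_item_pattern(12)
        doms = sorted(set(pattern))
        lam = pd.DataFrame(0.0, index=pattern.index, columns=doms + ["general"])
        for d in doms:
            lam.loc[pattern == d, d] = 0.6
        so = {d: 0.9999 for d in doms}
        model = BifactorModel(lam, np.zeros(12), "hierarchical", second_order=so)
        R = model.implied_corr()
        # rank-1 off-diagonal structure: all eigenvalues but one ~ tiny
        w = np.linalg.eigvalsh(R - np.diag(np.diag(R)))
        assert w[-1] > 10 * abs(w[-2])


class TestScoring:
    def test_balanced_subject_scores_near_zero(self):
        pattern = default_item_pattern(16)
        model = build_bifactor_truth(pattern, 0.5, 0.0,
                                     {d: 0.5 for d in set(pattern)})
        items = pd.DataFrame(
            np.tile([1, 0], (40, 8)), columns=model.item_ids)
        sc = score_map(items, model, orthogonalize=False)
        assert np.abs(sc["general"]).max() < 0.15

    def test_non_endorser_scores_negative_general(self):
        pattern = default_item_pattern(16)
        model = build_bifactor_truth(pattern, 0.6, 0.3,
                                     {d: 0.5 for d in set(pattern)})
        items = pd.DataFrame(np.zeros((5, 16), dtype=int),
                             columns=model.item_ids)
        sc = score_map(items, model, orthogonalize=False)
        assert (sc["general"] < 0).all()

    def test_all_missing_subject_gets_nan(self):
        pattern = default_item_pattern(12)
        model = build_bifactor_truth(pattern)
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 2, (6, 12)).astype(float)
        vals[2] = np.nan
        sc = score_map(pd.DataFrame(vals, columns=model.item_ids), model)
        assert sc.iloc[2].isna().all()
        assert np.isfinite(sc.drop(index=2).to_numpy()).all()

    def test_score_orthogonality_and_truth_correlation(self, bifactor_recovery):
        _, truth, eta, items, _, model = bifactor_recovery
        sc = score_map(items, model)
        C = np.corrcoef(sc[model.factor_names].to_numpy().T)
        assert np.abs(C[~np.eye(5, dtype=bool)]).max() < 0.2
        gi = truth.factor_names.index("general")
        r = np.corrcoef(sc["general"], eta[:, gi])[0, 1]
        assert r >= 0.80


class TestEstimatorAndIO:
    def test_estimator_fit_transform(self, bifactor_recovery):
        _, _, _, items, _, _ = bifactor_recovery
        est = BifactorEstimator(n_starts=2, seed=0).fit(items)
        sc = est.transform(items)
        assert sc.shape == (len(items), 5)
        assert est.loadings_.shape == (24, 5)
        params = est.get_params()
        assert params["variant"] == "bifactor"

    def test_model_json_round_trip(self, tmp_path, bifactor_recovery):
        *_, model = bifactor_recovery
        model.to_json(tmp_path / "m.json")
        back = BifactorModel.from_json(tmp_path / "m.json")
        pd.testing.assert_frame_equal(back.loadings, model.loadings)
        np.testing.assert_allclose(back.thresholds, model.thresholds)
        assert back.variant == model.variant

    def test_communality_bound_enforced(self):
        pattern = default_item_pattern(8)
        L = pd.DataFrame(0.9, index=pattern.index,
                         columns=sorted(set(pattern)) + ["general"])
        with pytest.raises(ValueError, match="communalit"):
            BifactorModel(L, np.zeros(8))
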
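"""Maximum-likelihood variance-component models on a relatedness matrix.

Implements the quantitative-genetic workhorses:

* univariate polygenic model — y ~ N(X b, sig2_g K + sig2_e I); heritability
  h2 = sig2_g / (sig2_g + sig2_e), tested against h2 = 0 with the boundary
  (1/2 chi2_0 + 1/2 chi2_1) likelihood-ratio null;
* bivariate polygenic model — genetic and environmental correlations rho_g,
  rho_e between two traits, with the phenotypic-correlation decomposition
  rho_p = rho_g sqrt(h2_1 h2_2) + rho_e sqrt((1-h2_1)(1-h2_2));
* Gene x Age interaction model — genetic variance log-linear in age,
  sig2_g(a) = exp(alpha_g + gamma_g (a - abar)), environmental analogue, and
  exponential decay exp(-lam |a_i - a_j|) of the cross-age genetic
  correlation; nonzero gamma means age-modulated genetic effects, nonzero
  lam means imperfect pleiotropy of the trait with itself across ages.

Estimation is maximum likelihood with fixed effects profiled out by GLS.
Likelihood evaluation exploits the family-block structure of the
relatedness matrix (connected components, batched by size through LAPACK);
a dense matrix degrades gracefully to a single block or, for the
univariate model, an eigendecomposition that is reused across traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from ._linalg import connected_blocks, group_blocks_by_size

__all__ = [
    "inverse_normal",
    "InverseNormalTransformer",
    "bh_fdr",
    "LRTResult",
    "lrt_nested",
    "PolygenicModel",
    "BivariateModel",
    "GxAgeModel",
    "fit_polygenic",
    "fit_bivariate",
    "fit_gxage",
    "variance_by_age",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# scalar utilities
# ---------------------------------------------------------------------------

def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset:
    Phi^{-1}((rank - 3/8) / (n + 1/4)); ties get average ranks, missing
    values are preserved."""
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = np.isfinite(x)
    n = int(obs.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    v = x[obs]
    if np.ptp(v) == 0:
        raise ValueError("all values identical: no ordering to transform")
    r = rankdata(v, method="average")
    out[obs] = norm.ppf((r - 0.375) / (n + 0.25))
    return out


class InverseNormalTransformer(BaseEstimator, TransformerMixin):
    """Column-wise rank-based inverse normal transform (Blom offset)."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return inverse_normal(X)
        return np.column_stack([inverse_normal(X[:, j]) for j in range(X.shape[1])])


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level q; returns (reject flags,
    adjusted p-values)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class LRTResult:
    """Likelihood-ratio test: statistic 2*(ll_full - ll_null) against chi2_1
    (interior parameter) or the 1/2 chi2_0 + 1/2 chi2_1 mixture (parameter on
    its boundary, e.g. a variance or decay rate at 0)."""

    statistic: float
    null: str  # 'chi2_1' or 'mixture'
    p_value: float


def lrt_nested(full, null, boundary: bool = False, tol: float = 1e-6) -> LRTResult:
    """LRT between nested fits (objects with ``loglik_`` or plain floats)."""
    ll_full = getattr(full, "loglik_", full)
    ll_null = getattr(null, "loglik_", null)
    stat = 2.0 * (ll_full - ll_null)
    if stat < -tol:
        raise ValueError(
            f"full log-likelihood below null by {-stat / 2:.3g}: refit needed")
    stat = max(stat, 0.0)
    if boundary:
        p = 0.5 * chi2.sf(stat, 1)
        return LRTResult(stat, "mixture", float(p))
    return LRTResult(stat, "chi2_1", float(chi2.sf(stat, 1)))


def _observed_info_se(fun, theta, h: float = 1e-4):
    """Delta-method-ready covariance from the observed information of a
    log-likelihood ``fun`` at ``theta`` (central finite differences)."""
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * h * h)
    info = -H
    try:
        cov = np.linalg.inv(info)
        if (np.diag(cov) <= 0).any():
            raise np.linalg.LinAlgError
        return cov
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)


# ---------------------------------------------------------------------------
# block-structured cohort container
# ---------------------------------------------------------------------------

class _Cohort:
    """Aligned (y, K, X, ages) with missing-phenotype rows dropped and the
    relatedness matrix decomposed into connected family blocks grouped by
    size for batched linear algebra."""

    def __init__(self, y, K, X=None, ages=None):
        y = np.asarray(y, dtype=float)
        K = K.values if hasattr(K, "values") and not isinstance(K, np.ndarray) else np.asarray(K)
        K = np.asarray(K, dtype=float)
        n0 = len(y)
        if K.shape != (n0, n0):
            raise ValueError("K must be N x N aligned with y")
        if X is None:
            X = np.ones((n0, 1))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
        if ages is not None:
            ages = np.asarray(ages, dtype=float)
            keep &= np.isfinite(ages)
            self.ages = ages[keep]
        else:
            self.ages = None
        idx = np.flatnonzero(keep)
        self.y = y[idx]
        self.X = X[idx]
        self.K = K[np.ix_(idx, idx)]
        self.n = len(idx)
        self.p = self.X.shape[1]
        if self.n < self.p + 2:
            raise ValueError("need at least n_covariates + 2 observations")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.p:
            raise ValueError("covariate design is rank-deficient")
        blocks = connected_blocks(self.K)
        self.groups = []  # (idx (m,b), K (m,b,b), X (m,b,p), y (m,b), ages)
        for b, idxmat in group_blocks_by_size(blocks).items():
            m = idxmat.shape[0]
            Kb = self.K[idxmat[:, :, None], idxmat[:, None, :]]
            Xb = self.X[idxmat]
            yb = self.y[idxmat]
            ab = self.ages[idxmat] if self.ages is not None else None
            self.groups.append((idxmat, Kb, Xb, yb, ab))

    # eigen representation for models with covariance s2g*K + s2e*I
    def eigen(self):
        if not hasattr(self, "_eig"):
            d_all = np.empty(self.n)
            yt = np.empty(self.n)
            Xt = np.empty_like(self.X)
            pos = 0
            for idxmat, Kb, Xb, yb, _ in self.groups:
                w, V = np.linalg.eigh(Kb)  # batched (m,b,b)
                m, b = yb.shape
                yt_b = np.einsum("mij,mi->mj", V, yb)
                Xt_b = np.einsum("mij,mip->mjp", V, Xb)
                cnt = m * b
                d_all[pos:pos + cnt] = w.reshape(-1)
                yt[pos:pos + cnt] = yt_b.reshape(-1)
                Xt[pos:pos + cnt] = Xt_b.reshape(-1, self.p)
                pos += cnt
            self._eig = (d_all, yt, Xt)
        return self._eig


# ---------------------------------------------------------------------------
# univariate polygenic model
# ---------------------------------------------------------------------------

class PolygenicModel(BaseEstimator):
    """Univariate polygenic ML fit: y ~ N(X b, sig2_g K + sig2_e I).

    The heritability ratio is profiled: for fixed h2 the GLS fixed effects
    and the total variance have closed forms, leaving a 1-D bounded
    maximization.  Fitted attributes: ``sigma2_g_``, ``sigma2_e_``,
    ``sigma2_p_``, ``h2_``, ``beta_``, ``beta_se_``, ``h2_se_``,
    ``loglik_``, ``loglik_null_`` (h2 = 0), ``lrt_h2_`` (boundary mixture).
    """

    def __init__(self, method: str = "ml"):
        self.method = method

    def fit(self, y, K, X=None):
        if self.method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")
        data = _Cohort(y, K, X)
        d, yt, Xt = data.eigen()
        n, p = data.n, data.p
        reml = self.method == "reml"
        dof = n - p if reml else n

        def profile(h2: float):
            w = h2 * d + (1.0 - h2)
            if (w <= 0).any():
                return -np.inf, None, None
            wi = 1.0 / w
            A = Xt.T @ (Xt * wi[:, None])
            bv = Xt.T @ (yt * wi)
            beta = np.linalg.solve(A, bv)
            r = yt - Xt @ beta
            rss = float(r @ (r * wi))
            s2p = rss / dof
            ll = -0.5 * (dof * np.log(s2p) + np.log(w).sum()
                         + dof + n * _LOG2PI) if not reml else None
            if reml:
                sign, logdetA = np.linalg.slogdet(A)
                ll = -0.5 * (dof * np.log(s2p) + np.log(w).sum() + logdetA
                             + dof + dof * _LOG2PI)
            return ll, beta, s2p

        res = optimize.minimize_scalar(
            lambda h: -profile(h)[0], bounds=(0.0, 1.0 - 1e-9),
            method="bounded", options={"xatol": 1e-9})
        candidates = [0.0, float(res.x), 1.0 - 1e-9]
        lls = [profile(h)[0] for h in candidates]
        best = int(np.argmax(lls))
        h2 = candidates[best]
        ll, beta, s2p = profile(h2)

        self.h2_ = float(h2 if h2 > 1e-8 else 0.0)
        self.sigma2_p_ = float(s2p)
        self.sigma2_g_ = float(self.h2_ * s2p)
        self.sigma2_e_ = float((1 - self.h2_) * s2p)
        self.beta_ = beta
        self.loglik_ = float(ll)
        self.loglik_null_ = float(profile(0.0)[0])
        self.lrt_h2_ = lrt_nested(self.loglik_, self.loglik_null_, boundary=True)
        self.n_ = n
        self.converged_ = True

        # beta SEs from the GLS covariance at the MLE
        w = self.h2_ * d + (1 - self.h2_)
        A = Xt.T @ (Xt / w[:, None])
        self.beta_cov_ = s2p * np.linalg.inv(A)
        self.beta_se_ = np.sqrt(np.diag(self.beta_cov_))

        # h2 SE: observed information on (log s2g, log s2e), delta method
        def ll_theta(th):
            s2g, s2e = np.exp(th)
            w_ = s2g * d + s2e
            wi = 1.0 / w_
            A_ = Xt.T @ (Xt * wi[:, None])
            b_ = np.linalg.solve(A_, Xt.T @ (yt * wi))
            r_ = yt - Xt @ b_
            return -0.5 * (np.log(w_).sum() + float(r_ @ (r_ * wi)) + n * _LOG2PI)

        if 0 < self.h2_ < 1 and self.sigma2_g_ > 1e-10:
            cov = _observed_info_se(
                ll_theta, np.log([self.sigma2_g_, self.sigma2_e_]))
            g = self.h2_ * (1 - self.h2_)
            var_h2 = g * g * (cov[0, 0] - 2 * cov[0, 1] + cov[1, 1])
            self.h2_se_ = float(np.sqrt(var_h2)) if var_h2 > 0 else np.nan
        else:
            self.h2_se_ = np.nan
        return self

    def predict(self, X):
        """Fixed-effect mean X b."""
        return np.asarray(X, dtype=float) @ self.beta_


def fit_polygenic(y, K, X=None, method: str = "ml") -> PolygenicModel:
    """Thin wrapper over :class:`PolygenicModel`."""
    return PolygenicModel(method=method).fit(y, K, X)


# ---------------------------------------------------------------------------
# Gene x Age model
# ---------------------------------------------------------------------------

def _gxage_omega_pieces(theta, Kb, ab, abar):
    """Per-group covariance Omega and the elementwise pieces needed for
    gradients.  theta = (alpha_g, gamma_g, alpha_e, gamma_e, lam)."""
    ag, gg, ae, ge, lam = theta
    dev = ab - abar  # (m, b)
    sg = np.exp(0.5 * (ag + gg * dev))
    se2 = np.exp(ae + ge * dev)
    gap = np.abs(ab[:, :, None] - ab[:, None, :])
    G = Kb * (sg[:, :, None] * sg[:, None, :]) * np.exp(-lam * gap)
    omega = G.copy()
    diag = np.arange(Kb.shape[1])
    omega[:, diag, diag] += se2
    return omega, G, gap, dev, se2


class GxAgeModel(BaseEstimator):
    """Gene x Age variance-component ML fit.

    Covariance: Omega_ij = K_ij sig_g(a_i) sig_g(a_j) exp(-lam |a_i - a_j|)
    + 1[i=j] sig2_e(a_i), with log-linear age trends
    sig2_g(a) = exp(alpha_g + gamma_g (a - abar)) and the environmental
    analogue; lam >= 0.  Fixed effects profiled by GLS; analytic gradients;
    seeded multi-start quasi-Newton.

    Fitted attributes: ``alpha_g_``, ``gamma_g_``, ``alpha_e_``,
    ``gamma_e_``, ``lambda_``, ``ref_age_``, ``beta_``, ``loglik_``, ``se_``
    (dict), and nested LRTs ``lrt_gamma_g_`` / ``lrt_gamma_e_`` (interior
    chi2_1) and ``lrt_lambda_`` (boundary mixture).
    """

    _PNAMES = ("alpha_g", "gamma_g", "alpha_e", "gamma_e", "lambda")

    def __init__(self, n_starts: int = 3, seed: int = 0, ref_age: float | None = None,
                 lambda_max: float = 2.0, compute_lrts: bool = True,
                 compute_se: bool = True,
                 lrts: tuple = ("gamma_g", "gamma_e", "lambda")):
        self.n_starts = n_starts
        self.seed = seed
        self.ref_age = ref_age
        self.lambda_max = lambda_max
        self.compute_lrts = compute_lrts
        self.compute_se = compute_se
        self.lrts = lrts

    # -- profiled log-likelihood and gradient -----------------------------
    def _loglik_grad(self, theta, data, abar, want_grad=True):
        n, p = data.n, data.p
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        logdet = 0.0
        cache = []
        for idxmat, Kb, Xb, yb, ab in data.groups:
            omega, G, gap, dev, se2 = _gxage_omega_pieces(theta, Kb, ab, abar)
            try:
                L = np.linalg.cholesky(omega)
            except np.linalg.LinAlgError:
                return -np.inf, np.zeros(5), None
            logdet += 2.0 * float(np.log(np.einsum("mii->mi", L)).sum())
            oinv = np.linalg.inv(omega)
            A += np.einsum("mip,mij,mjq->pq", Xb, oinv, Xb)
            bvec += np.einsum("mip,mij,mj->p", Xb, oinv, yb)
            cache.append((oinv, G, gap, dev, se2, Xb, yb))
        beta = np.linalg.solve(A, bvec)
        quad = 0.0
        grad = np.zeros(5)
        for (oinv, G, gap, dev, se2, Xb, yb) in cache:
            r = yb - np.einsum("mip,p->mi", Xb, beta)
            u = np.einsum("mij,mj->mi", oinv, r)
            quad += float(np.einsum("mi,mi->", r, u))
            if want_grad:
                davg = 0.5 * (dev[:, :, None] + dev[:, None, :])
                douts = (
                    G,                      # d/d alpha_g
                    G * davg,               # d/d gamma_g
                    None, None,             # diagonal pieces below
                    -G * gap,               # d/d lambda
                )
                for k, dO in ((0, douts[0]), (1, douts[1]), (4, douts[4])):
                    tr = float(np.einsum("mij,mij->", oinv, dO))
                    qf = float(np.einsum("mi,mij,mj->", u, dO, u))
                    grad[k] += -0.5 * tr + 0.5 * qf
                # diagonal environmental derivatives
                odiag = np.einsum("mii->mi", oinv)
                u2 = u * u
                grad[2] += -0.5 * float((odiag * se2).sum()) + 0.5 * float((u2 * se2).sum())
                grad[3] += (-0.5 * float((odiag * se2 * dev).sum())
                            + 0.5 * float((u2 * se2 * dev).sum()))
        ll = -0.5 * (logdet + quad + n * _LOG2PI)
        return ll, (grad if want_grad else None), beta

    def _optimize(self, data, abar, fixed_idx, extra_starts=()):
        """Multi-start bounded quasi-Newton over the free parameters;
        returns (theta, loglik, beta, success)."""
        free = np.array([i for i in range(5) if i not in fixed_idx])

        # moment-based start from the static polygenic fit
        base = PolygenicModel().fit(data.y, data.K, data.X)
        th0 = np.array([
            np.log(max(base.sigma2_g_, 1e-3)), 0.0,
            np.log(max(base.sigma2_e_, 1e-3)), 0.0, 0.0,
        ])
        for i, v in fixed_idx.items():
            th0[i] = v

        bounds_all = [(-20, 20), (-2, 2), (-20, 20), (-2, 2), (0.0, self.lambda_max)]
        lo = np.array([bounds_all[i][0] for i in free])
        hi = np.array([bounds_all[i][1] for i in free])
        rng = np.random.default_rng(self.seed)

        def pack(th_free):
            th = th0.copy()
            th[free] = th_free
            return th

        def neg(th_free):
            ll, g, _beta = self._loglik_grad(pack(th_free), data, abar)
            if not np.isfinite(ll):
                return 1e10, np.zeros(len(free))
            return -ll, -g[free]

        starts = [th0[free].copy()]
        for s in range(1, max(1, self.n_starts)):
            starts.append(np.clip(th0[free] + rng.uniform(-0.3, 0.3, len(free)),
                                  lo, hi))
        for th in extra_starts:
            starts.append(np.clip(np.asarray(th)[free], lo, hi))

        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg, x0, jac=True, method="L-BFGS-B",
                bounds=[bounds_all[i] for i in free],
                options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8})
            if best is None or res.fun < best.fun:
                best = res
        theta = pack(best.x)
        ll, _, beta = self._loglik_grad(theta, data, abar, want_grad=False)
        return theta, float(ll), beta, bool(best.success)

    def _store(self, theta, ll, beta, success, abar, n):
        self.alpha_g_, self.gamma_g_, self.alpha_e_, self.gamma_e_, self.lambda_ = \
            (float(t) for t in theta)
        self.ref_age_ = abar
        self.beta_ = beta
        self.loglik_ = float(ll)
        self.converged_ = success
        self.n_ = n
        self.theta_ = theta
        self.sigma2_g0_ = float(np.exp(self.alpha_g_))
        self.sigma2_e0_ = float(np.exp(self.alpha_e_))
        self.lambda_at_bound_ = bool(self.lambda_ >= self.lambda_max - 1e-6)
        if self.lambda_at_bound_:
            import warnings
            warnings.warn("lambda pinned at its upper bound")

    def fit(self, y, K, ages, X=None, fix: dict | None = None):
        """Fit; ``fix`` maps parameter names ('gamma_g', 'gamma_e', 'lambda')
        to fixed values for constrained null fits."""
        data = _Cohort(y, K, X, ages=ages)
        abar = self.ref_age if self.ref_age is not None else float(data.ages.mean())
        fix = dict(fix or {})
        fixed_idx = {self._PNAMES.index(k.replace("lam", "lambda") if k == "lam" else k): float(v)
                     for k, v in fix.items()}
        theta, ll, beta, success = self._optimize(data, abar, fixed_idx)
        self._store(theta, ll, beta, success, abar, data.n)

        if self.compute_lrts and not fix:
            if "gamma_g" in self.lrts:
                self.lrt_gamma_g_ = self._nested_lrt(data, abar, {"gamma_g": 0.0}, False)
            if "gamma_e" in self.lrts:
                self.lrt_gamma_e_ = self._nested_lrt(data, abar, {"gamma_e": 0.0}, False)
            if "lambda" in self.lrts:
                self.lrt_lambda_ = self._nested_lrt(data, abar, {"lambda": 0.0}, True)

        if self.compute_se:
            free_se = [i for i in range(5) if i not in fixed_idx]
            # drop lambda from the information when it sits on its boundary
            if self.lambda_ < 1e-8 and 4 in free_se:
                free_se.remove(4)

            def ll_of(th_sub):
                th = self.theta_.copy()
                th[free_se] = th_sub
                return self._loglik_grad(th, data, abar, want_grad=False)[0]

            cov = _observed_info_se(ll_of, self.theta_[free_se])
            se = {name: np.nan for name in self._PNAMES}
            for k, i in enumerate(free_se):
                se[self._PNAMES[i]] = float(np.sqrt(cov[k, k])) if np.isfinite(
                    cov[k, k]) else np.nan
            self.se_ = se
        return self

    def _nested_lrt(self, data, abar, fix, boundary):
        """Constrained null fit on the same data; if the null ends above the
        incumbent full fit (a local optimum), the full model is refit from
        the null's solution before the test is formed."""
        fixed_idx = {self._PNAMES.index(k): float(v) for k, v in fix.items()}
        null = GxAgeModel(n_starts=self.n_starts, seed=self.seed,
                          ref_age=abar, lambda_max=self.lambda_max,
                          compute_lrts=False, compute_se=False)
        th, ll, beta, success = null._optimize(data, abar, fixed_idx)
        null._store(th, ll, beta, success, abar, data.n)
        if null.loglik_ > self.loglik_ + 1e-9:
            theta, ll_f, beta_f, succ = self._optimize(
                data, abar, {}, extra_starts=[null.theta_])
            if ll_f > self.loglik_:
                self._store(theta, ll_f, beta_f, succ, abar, data.n)
        return lrt_nested(self.loglik_, null.loglik_, boundary=boundary)


def fit_gxage(y, K, ages, X=None, n_starts: int = 3, seed: int = 0,
              ref_age: float | None = None, **kw) -> GxAgeModel:
    """Thin wrapper over :class:`GxAgeModel`."""
    return GxAgeModel(n_starts=n_starts, seed=seed, ref_age=ref_age, **kw).fit(
        y, K, ages, X)


def variance_by_age(fit: GxAgeModel, age_grid) -> "pd.DataFrame":
    """Per-age genetic variance, environmental variance, and heritability
    curves implied by a Gene x Age fit."""
    import pandas as pd

    a = np.asarray(age_grid, dtype=float)
    s2g = np.exp(fit.alpha_g_ + fit.gamma_g_ * (a - fit.ref_age_))
    s2e = np.exp(fit.alpha_e_ + fit.gamma_e_ * (a - fit.ref_age_))
    return pd.DataFrame({
        "age": a,
        "sigma2_g": s2g,
        "sigma2_e": s2e,
        "h2": s2g / (s2g + s2e),
    })


# ---------------------------------------------------------------------------
# bivariate polygenic model
# ---------------------------------------------------------------------------

def _z2r(z):
    return np.tanh(z)


def _r2z(r):
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


class BivariateModel(BaseEstimator):
    """Bivariate polygenic ML fit for genetic / environmental correlations.

    Stacked covariance: genetic block [[s2g1 K, rg sg1 sg2 K],
    [., s2g2 K]], environmental block diagonal per individual with
    cross-trait re se1 se2.  Subjects missing one trait contribute the
    observed part of their stacked vector to the likelihood.

    Fitted attributes: per-trait ``sigma2_g_``, ``sigma2_e_``, ``h2_``
    (arrays of length 2), ``rho_g_``, ``rho_e_``, ``rho_p_``, ``loglik_``,
    ``lrt_rho_g_``, ``lrt_rho_e_`` (interior chi2_1), and ``se_`` (dict with
    rho_g / rho_e standard errors).
    """

    def __init__(self, n_starts: int = 3, seed: int = 0, compute_lrts: bool = True,
                 compute_se: bool = True):
        self.n_starts = n_starts
        self.seed = seed
        self.compute_lrts = compute_lrts
        self.compute_se = compute_se

    # complete-data path: rotate by the eigenvectors of K, leaving
    # independent 2x2 per-individual covariances C_i = d_i * G + E
    def _loglik_eigen(self, theta, d, Y, Xt, fix_rg, fix_re):
        s2g1, s2e1, s2g2, s2e2 = np.exp(theta[:4])
        rg = fix_rg if fix_rg is not None else _z2r(theta[4])
        re_ = fix_re if fix_re is not None else _z2r(theta[5 - (fix_rg is not None)])
        cg = rg * np.sqrt(s2g1 * s2g2)
        ce = re_ * np.sqrt(s2e1 * s2e2)
        c11 = s2g1 * d + s2e1
        c22 = s2g2 * d + s2e2
        c12 = cg * d + ce
        det = c11 * c22 - c12 * c12
        if (det <= 0).any() or (c11 <= 0).any():
            return -np.inf, None
        # GLS for stacked beta = (beta1, beta2)
        w11 = c22 / det
        w22 = c11 / det
        w12 = -c12 / det
        p = Xt.shape[1]
        A = np.zeros((2 * p, 2 * p))
        A[:p, :p] = Xt.T @ (Xt * w11[:, None])
        A[p:, p:] = Xt.T @ (Xt * w22[:, None])
        A[:p, p:] = Xt.T @ (Xt * w12[:, None])
        A[p:, :p] = A[:p, p:].T
        rhs = np.concatenate([
            Xt.T @ (w11 * Y[0] + w12 * Y[1]),
            Xt.T @ (w12 * Y[0] + w22 * Y[1]),
        ])
        beta = np.linalg.solve(A, rhs)
        r1 = Y[0] - Xt @ beta[:p]
        r2 = Y[1] - Xt @ beta[p:]
        quad = float((w11 * r1 * r1 + 2 * w12 * r1 * r2 + w22 * r2 * r2).sum())
        n = len(d)
        ll = -0.5 * (np.log(det).sum() + quad + 2 * n * _LOG2PI)
        return ll, beta

    # general path: per family block, stacked observed entries
    def _loglik_blocks(self, theta, blocks, fix_rg, fix_re):
        s2g1, s2e1, s2g2, s2e2 = np.exp(theta[:4])
        rg = fix_rg if fix_rg is not None else _z2r(theta[4])
        re_ = fix_re if fix_re is not None else _z2r(theta[5 - (fix_rg is not None)])
        cg = rg * np.sqrt(s2g1 * s2g2)
        ce = re_ * np.sqrt(s2e1 * s2e2)
        p = blocks[0][1].shape[1]
        A = np.zeros((2 * p, 2 * p))
        rhs = np.zeros(2 * p)
        logdet = 0.0
        cache = []
        ntot = 0
        for (Kb, Xb, y1, y2, o1, o2) in blocks:
            b = Kb.shape[0]
            Ib = np.eye(b)
            top = np.hstack([s2g1 * Kb + s2e1 * Ib, cg * Kb + ce * Ib])
            bot = np.hstack([cg * Kb + ce * Ib, s2g2 * Kb + s2e2 * Ib])
            omega = np.vstack([top, bot])
            obs = np.concatenate([o1, o2 + b])
            omega = omega[np.ix_(obs, obs)]
            Z = np.zeros((len(obs), 2 * p))
            n1 = len(o1)
            Z[:n1, :p] = Xb[o1]
            Z[n1:, p:] = Xb[o2]
            yv = np.concatenate([y1[o1], y2[o2]])
            try:
                L = np.linalg.cholesky(omega)
            except np.linalg.LinAlgError:
                return -np.inf, None
            logdet += 2.0 * float(np.log(np.diag(L)).sum())
            oinv = np.linalg.inv(omega)
            A += Z.T @ oinv @ Z
            rhs += Z.T @ (oinv @ yv)
            cache.append((oinv, Z, yv))
            ntot += len(obs)
        beta = np.linalg.solve(A, rhs)
        quad = 0.0
        for (oinv, Z, yv) in cache:
            r = yv - Z @ beta
            quad += float(r @ oinv @ r)
        ll = -0.5 * (logdet + quad + ntot * _LOG2PI)
        return ll, beta

    def fit(self, y1, y2, K, X=None, fix_rho_g: float | None = None,
            fix_rho_e: float | None = None):
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        K = K.values if hasattr(K, "values") and not isinstance(K, np.ndarray) else np.asarray(K)
        n0 = len(y1)
        if X is None:
            X = np.ones((n0, 1))
        X = np.asarray(X, dtype=float)
        keep = (np.isfinite(y1) | np.isfinite(y2)) & np.isfinite(X).all(axis=1)
        idx = np.flatnonzero(keep)
        y1, y2, X = y1[idx], y2[idx], X[idx]
        K = np.asarray(K, dtype=float)[np.ix_(idx, idx)]
        complete = np.isfinite(y1).all() and np.isfinite(y2).all()

        if complete:
            data = _Cohort(y1, K, X)
            d, _, Xt = data.eigen()
            # rotate both traits with the same blockwise eigenvectors
            Y = np.empty((2, data.n))
            pos = 0
            for idxmat, Kb, Xb, yb, _ in data.groups:
                w, V = np.linalg.eigh(Kb)
                m, b = yb.shape
                Y[0, pos:pos + m * b] = np.einsum("mij,mi->mj", V, y1[idxmat]).reshape(-1)
                Y[1, pos:pos + m * b] = np.einsum("mij,mi->mj", V, y2[idxmat]).reshape(-1)
                pos += m * b
            loglik = lambda th: self._loglik_eigen(th, d, Y, Xt, fix_rho_g, fix_rho_e)
        else:
            blocks = []
            for ix in connected_blocks(K):
                o1 = np.flatnonzero(np.isfinite(y1[ix]))
                o2 = np.flatnonzero(np.isfinite(y2[ix]))
                blocks.append((K[np.ix_(ix, ix)], X[ix],
                               np.nan_to_num(y1[ix]), np.nan_to_num(y2[ix]), o1, o2))
            loglik = lambda th: self._loglik_blocks(th, blocks, fix_rho_g, fix_rho_e)

        nfree = 4 + (fix_rho_g is None) + (fix_rho_e is None)
        v1 = np.nanvar(y1)
        v2 = np.nanvar(y2)
        th0 = np.array([np.log(0.4 * v1), np.log(0.6 * v1),
                        np.log(0.4 * v2), np.log(0.6 * v2)] + [0.0] * (nfree - 4))

        rng = np.random.default_rng(self.seed)

        def neg(th):
            ll, _ = loglik(th)
            return -ll if np.isfinite(ll) else 1e10

        best = None
        for s in range(max(1, self.n_starts)):
            x0 = th0 if s == 0 else th0 + rng.uniform(-0.3, 0.3, nfree)
            res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                    options={"maxiter": 800, "ftol": 1e-13})
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        ll, beta = loglik(theta)

        s2 = np.exp(theta[:4])
        self.sigma2_g_ = np.array([s2[0], s2[2]])
        self.sigma2_e_ = np.array([s2[1], s2[3]])
        self.h2_ = self.sigma2_g_ / (self.sigma2_g_ + self.sigma2_e_)
        self.rho_g_ = float(fix_rho_g if fix_rho_g is not None else _z2r(theta[4]))
        ipos = 5 - (fix_rho_g is not None)
        self.rho_e_ = float(fix_rho_e if fix_rho_e is not None else _z2r(theta[ipos]))
        self.rho_p_ = float(
            self.rho_g_ * np.sqrt(self.h2_[0] * self.h2_[1])
            + self.rho_e_ * np.sqrt((1 - self.h2_[0]) * (1 - self.h2_[1])))
        self.beta_ = beta
        self.loglik_ = float(ll)
        self.converged_ = bool(best.success)
        self.n_ = len(idx)

        if self.compute_se and fix_rho_g is None and fix_rho_e is None:
            cov = _observed_info_se(lambda th: loglik(th)[0], theta, h=1e-3)
            dz_g = 1 - self.rho_g_**2  # d tanh(z)/dz
            dz_e = 1 - self.rho_e_**2
            self.se_ = {
                "rho_g": float(np.sqrt(cov[4, 4]) * dz_g) if np.isfinite(cov[4, 4]) else np.nan,
                "rho_e": float(np.sqrt(cov[5, 5]) * dz_e) if np.isfinite(cov[5, 5]) else np.nan,
            }

        if self.compute_lrts and fix_rho_g is None and fix_rho_e is None:
            y1o = np.where(np.isfinite(y1), y1, np.nan)
            y2o = np.where(np.isfinite(y2), y2, np.nan)
            null_g = BivariateModel(self.n_starts, self.seed, False, False).fit(
                y1o, y2o, K, X, fix_rho_g=0.0)
            null_e = BivariateModel(self.n_starts, self.seed, False, False).fit(
                y1o, y2o, K, X, fix_rho_e=0.0)
            self.lrt_rho_g_ = lrt_nested(self.loglik_, null_g.loglik_, boundary=False)
            self.lrt_rho_e_ = lrt_nested(self.loglik_, null_e.loglik_, boundary=False)
        return self


def fit_bivariate(y1, y2, K, X=None, n_starts: int = 3, seed: int = 0,
                  **kw) -> BivariateModel:
    """Thin wrapper over :class:`BivariateModel`."""
    return BivariateModel(n_starts=n_starts, seed=seed, **kw).fit(y1, y2, K, X)
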
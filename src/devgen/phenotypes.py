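"""Analysis-ready trait tables: eligibility filtering, chained-equation
imputation with predictive mean matching, PCA composite scores, and the
covariate design (age, age squared, sex, and their interactions)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "eligibility_filter",
    "ChainedImputer",
    "chained_impute",
    "pca_composite",
    "build_covariates",
]


def eligibility_filter(
    table: pd.DataFrame,
    trait_columns: list[str],
    max_missing_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects missing >= ``max_missing_fraction`` of the trait columns
    (the study's "<50% cognitive data" eligibility rule keeps only subjects
    missing strictly less than half).

    Returns (filtered table, log DataFrame of removed rows with their
    missing fractions).
    """
    frac = table[trait_columns].isna().mean(axis=1)
    keep = frac < max_missing_fraction
    log = pd.DataFrame({
        "iid": table.loc[~keep, "iid"] if "iid" in table.columns else table.index[~keep],
        "missing_fraction": frac[~keep],
    }).reset_index(drop=True)
    return table.loc[keep].reset_index(drop=True), log


class ChainedImputer(BaseEstimator, TransformerMixin):
    """Multivariate imputation by chained equations with predictive mean
    matching (PMM).

    Each incomplete column is iteratively regressed (OLS) on age, sex, and
    all other trait columns; a missing entry receives the observed value of
    one of the ``n_donors`` donors whose predicted means are closest to the
    entry's predicted mean.  A single completed table is returned; observed
    entries are never altered, and every imputed value is an element of the
    column's observed donor pool.

    Parameters
    ----------
    n_iterations : chained passes over the columns (default 10)
    n_donors : PMM donor-pool size (default 5)
    seed : donor-choice randomness; imputation is deterministic given it
    """

    def __init__(self, n_iterations: int = 10, n_donors: int = 5, seed: int = 0):
        self.n_iterations = n_iterations
        self.n_donors = n_donors
        self.seed = seed

    def fit(self, X, y=None):
        # stateless between tables: chained equations are re-estimated on
        # each transform; fit records the column layout only
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        return self

    def transform(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return self._impute(X)

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def _impute(self, table: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        work = table.astype(float).copy()
        miss = work.isna()
        if not miss.any().any():
            return work
        empty = [c for c in work.columns if miss[c].all()]
        if empty:
            raise ValueError(f"columns with no observed values: {empty}")

        # initialize missing entries at column means
        work = work.fillna(work.mean())
        incomplete = [c for c in work.columns if miss[c].any()]
        V = work.to_numpy()
        cols = list(work.columns)
        for _ in range(self.n_iterations):
            for c in incomplete:
                j = cols.index(c)
                m = miss[c].to_numpy()
                others = [k for k in range(V.shape[1]) if k != j]
                A = np.column_stack([np.ones(len(V)), V[:, others]])
                obs = ~m
                beta, *_ = np.linalg.lstsq(A[obs], V[obs, j], rcond=None)
                pred = A @ beta
                # PMM: match each missing prediction to nearest observed preds
                obs_pred = pred[obs]
                obs_val = V[obs, j]
                order = np.argsort(obs_pred)
                sorted_pred = obs_pred[order]
                sorted_val = obs_val[order]
                for i in np.flatnonzero(m):
                    pos = np.searchsorted(sorted_pred, pred[i])
                    lo = max(0, pos - self.n_donors)
                    hi = min(len(sorted_pred), pos + self.n_donors)
                    cand = np.arange(lo, hi)
                    nearest = cand[np.argsort(np.abs(sorted_pred[cand] - pred[i]))][: self.n_donors]
                    V[i, j] = sorted_val[nearest[rng.integers(len(nearest))]]
        out = pd.DataFrame(V, columns=cols, index=table.index)
        out[~miss] = table[~miss]  # observed entries preserved exactly
        return out


def chained_impute(
    table: pd.DataFrame,
    trait_columns: list[str],
    n_iterations: int = 10,
    n_donors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Impute the trait columns of ``table`` using age, sex, and the other
    trait columns as predictors (see :class:`ChainedImputer`)."""
    predictors = [c for c in ("age", "sex") if c in table.columns]
    sub = table[predictors + list(trait_columns)]
    if sub[predictors].isna().any().any():
        raise ValueError("age/sex predictors must be complete")
    imputer = ChainedImputer(n_iterations=n_iterations, n_donors=n_donors, seed=seed)
    completed = imputer.fit_transform(sub)
    out = table.copy()
    out[trait_columns] = completed[trait_columns]
    return out


def pca_composite(
    table: pd.DataFrame,
    columns: list[str],
    orientation_anchor: str | None = None,
) -> pd.Series:
    """First-principal-component score of the named columns.

    Columns are standardized to zero mean / unit variance first; the score is
    scaled to unit variance and sign-oriented so the anchor column's loading
    (default: the first column) is positive.
    """
    if len(columns) < 2:
        raise ValueError("need at least 2 columns for a composite")
    X = table[list(columns)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("composite columns must be complete (impute first)")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [c for c, s in zip(columns, sd) if s == 0]
        raise ValueError(f"zero-variance columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=1)
    score = pca.fit_transform(Z)[:, 0]
    anchor = orientation_anchor or columns[0]
    if pca.components_[0, list(columns).index(anchor)] < 0:
        score = -score
    score = score / score.std(ddof=1)
    return pd.Series(score, index=table.index, name="pc1")


def build_covariates(ages, sexes) -> pd.DataFrame:
    """Fixed-effect design: intercept, centered age, centered age squared,
    sex (0/1), and the age x sex and age^2 x sex interactions."""
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    sex01 = (sexes == 2).astype(float) if set(np.unique(sexes)) <= {1, 2} \
        else sexes.astype(float)
    a = ages - ages.mean()
    X = pd.DataFrame({
        "intercept": np.ones(len(ages)),
        "age_c": a,
        "age_c2": a**2,
        "sex": sex01,
        "age_c_x_sex": a * sex01,
        "age_c2_x_sex": a**2 * sex01,
    })
    return X
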
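"""Genetic relatedness matrices: LD pruning, the standardized-dosage GRM,
pedigree kinship, property validation, and GRM file I/O.

The empirical estimator is the standard allele-frequency-standardized GRM

    K_ij = (1/M) * sum_m (x_im - 2 p_m)(x_jm - 2 p_m) / (2 p_m (1 - p_m)),

averaged over SNPs observed in both individuals, on the same 2*Phi scale as
the pedigree numerator relationship matrix, so either can feed the
variance-component models interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, kinship_from_pedigree

__all__ = [
    "RelatednessMatrix",
    "GRMValidation",
    "ld_prune",
    "empirical_grm",
    "pedigree_grm",
    "validate_grm",
    "read_grm",
    "write_grm",
]


@dataclass
class RelatednessMatrix:
    """N x N symmetric relatedness with individual ids and provenance
    ('empirical' or 'pedigree')."""

    ids: np.ndarray
    values: np.ndarray
    provenance: str = "empirical"
    n_snps: int | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match number of ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "RelatednessMatrix":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        ix = np.array([pos[i] for i in keep_ids])
        return RelatednessMatrix(np.asarray(keep_ids), self.values[np.ix_(ix, ix)],
                                 self.provenance, self.n_snps)

    def sparsified(self, cutoff: float = 0.05) -> "RelatednessMatrix":
        """Zero off-diagonals with |K_ij| < cutoff (unrelated-pair noise),
        restoring family-block structure to an empirical GRM."""
        V = self.values.copy()
        mask = np.abs(V) < cutoff
        np.fill_diagonal(mask, False)
        V[mask] = 0.0
        return RelatednessMatrix(self.ids, V, self.provenance, self.n_snps)


def pedigree_grm(ped: Pedigree) -> RelatednessMatrix:
    """Expected relationship matrix 2*Phi from pedigree structure."""
    A, ids = kinship_from_pedigree(ped)
    return RelatednessMatrix(ids, A, provenance="pedigree")


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    G: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_snps: int = 50,
) -> GenotypeMatrix:
    """Greedy left-to-right windowed pruning toward approximate linkage
    equilibrium: the later SNP of any within-window pair with squared dosage
    correlation above the threshold is dropped.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2 threshold must be in (0, 1]")
    X = G.dosages
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 SNPs to prune")

    col_mean = np.nanmean(X, axis=0)
    usable = np.ones(m, dtype=bool)
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        warnings.warn(f"excluding {int(all_missing.sum())} all-missing SNP columns")
        usable &= ~all_missing

    Xc = X - col_mean[None, :]
    Xc = np.where(np.isnan(Xc), 0.0, Xc)  # mean-impute for correlation only
    norms = np.sqrt((Xc**2).sum(axis=0))

    kept: list[int] = []
    active: list[int] = []  # kept SNPs still inside the sliding window
    for j in range(m):
        if not usable[j] or norms[j] == 0:
            if norms[j] == 0 and usable[j]:
                kept.append(j)  # monomorphic: no LD signal, keep as-is
                active.append(j)
            continue
        active = [k for k in active if j - k < window_snps]
        drop = False
        comp = [k for k in active if norms[k] > 0]
        if comp:
            r = (Xc[:, comp].T @ Xc[:, j]) / (norms[comp] * norms[j])
            drop = bool((r**2 > r2_threshold).any())
        if not drop:
            kept.append(j)
            active.append(j)
    return G.subset_snps(np.asarray(kept, dtype=int))


# ---------------------------------------------------------------------------
# empirical GRM
# ---------------------------------------------------------------------------

def empirical_grm(G: GenotypeMatrix, min_snps: int = 2) -> RelatednessMatrix:
    """Allele-frequency-standardized dosage GRM.

    Frequencies come from the sample itself; monomorphic SNPs are skipped;
    missing dosages are handled by pairwise-complete averaging (per-pair SNP
    counts), keeping the estimator unbiased under MCAR.
    """
    X = G.dosages
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if poly.sum() < min_snps:
        raise ValueError(f"need >= {min_snps} polymorphic SNPs with data")
    X = X[:, poly]
    p = p[poly]

    Z = (X - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    obs = ~np.isnan(Z)
    Zf = np.where(obs, Z, 0.0)
    num = Zf @ Zf.T
    counts = obs.astype(float) @ obs.astype(float).T
    if (counts < 1).any():
        raise ValueError("some individual pairs share no observed SNPs")
    K = num / counts
    K = 0.5 * (K + K.T)
    return RelatednessMatrix(G.ids.copy(), K, provenance="empirical",
                             n_snps=int(poly.sum()))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class GRMValidation:
    """Property report for a relatedness matrix."""

    max_asymmetry: float
    min_eigenvalue: float
    trace_over_n: float
    diag_range: tuple[float, float]
    offdiag_range: tuple[float, float]
    checks: dict

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


def validate_grm(
    K: RelatednessMatrix,
    psd_tol: float = 1e-8,
    trace_tol: float = 0.1,
    offdiag_bounds: tuple[float, float] = (-0.2, 1.2),
) -> GRMValidation:
    """Check symmetry, positive semi-definiteness, trace ~= N, and entry
    ranges; always returns a report rather than raising."""
    V = K.values
    asym = float(np.abs(V - V.T).max())
    Vs = 0.5 * (V + V.T)
    min_eig = float(np.linalg.eigvalsh(Vs).min())
    tr_n = float(np.trace(V) / K.n)
    d = np.diag(V)
    off = V[~np.eye(K.n, dtype=bool)] if K.n > 1 else np.array([0.0])
    checks = {
        "symmetric": asym < 1e-8,
        "psd": min_eig > -psd_tol,
        "trace": (abs(tr_n - 1.0) < trace_tol) if K.provenance == "empirical" else True,
        "offdiag_range": bool((off >= offdiag_bounds[0]).all()
                              and (off <= offdiag_bounds[1]).all()),
    }
    return GRMValidation(
        max_asymmetry=asym,
        min_eigenvalue=min_eig,
        trace_over_n=tr_n,
        diag_range=(float(d.min()), float(d.max())),
        offdiag_range=(float(off.min()), float(off.max())),
        checks=checks,
    )


# ---------------------------------------------------------------------------
# I/O: GCTA-style lower-triangle text + id file, or square TSV
# ---------------------------------------------------------------------------

def write_grm(K: RelatednessMatrix, path: str, dialect: str = "gcta") -> None:
    """``gcta``: ``<path>.grm`` with columns i, j, n_snps, value (1-based,
    lower triangle incl. diagonal) plus ``<path>.grm.id``; ``square``:
    one TSV with header ids."""
    if dialect == "gcta":
        n = K.n
        rows = []
        nsnp = K.n_snps if K.n_snps is not None else 0
        for i in range(n):
            for j in range(i + 1):
                rows.append((i + 1, j + 1, nsnp, K.values[i, j]))
        pd.DataFrame(rows).to_csv(f"{path}.grm", sep="\t", header=False,
                                  index=False, float_format="%.17g")
        pd.DataFrame({"fid": K.ids, "iid": K.ids}).to_csv(
            f"{path}.grm.id", sep="\t", header=False, index=False)
    elif dialect == "square":
        df = pd.DataFrame(K.values, columns=K.ids)
        df.insert(0, "iid", K.ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown GRM dialect: {dialect}")


def read_grm(path: str, dialect: str = "gcta") -> RelatednessMatrix:
    if dialect == "gcta":
        ids = pd.read_csv(f"{path}.grm.id", sep="\t", header=None)[1].astype(str).to_numpy()
        tri = pd.read_csv(f"{path}.grm", sep="\t", header=None,
                          names=["i", "j", "nsnp", "value"])
        n = int(tri["i"].max())
        if n != len(ids):
            raise ValueError("id file length does not match matrix dimension")
        V = np.zeros((n, n))
        V[tri["i"] - 1, tri["j"] - 1] = tri["value"]
        V = V + np.tril(V, -1).T
        nsnp = int(tri["nsnp"].iloc[0]) or None
        return RelatednessMatrix(ids, V, provenance="empirical", n_snps=nsnp)
    if dialect == "square":
        df = pd.read_csv(path, sep="\t")
        ids = df["iid"].astype(str).to_numpy()
        V = df.drop(columns="iid").to_numpy(dtype=float)
        if V.shape != (len(ids), len(ids)):
            raise ValueError("square GRM file is not N x N")
        return RelatednessMatrix(ids, V, provenance="empirical")
    raise ValueError(f"unknown GRM dialect: {dialect}")
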
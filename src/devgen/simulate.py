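"""Synthetic cohort generator.

Emulates, at configurable scale, a population-based developmental cohort:
nuclear families plus unrelated singletons aged 8-21; Mendelianly transmitted
SNP dosages with blockwise linkage disequilibrium; binary psychiatric symptom
items generated from a bifactor structure (general + anxious-misery,
externalizing, fear, psychosis-spectrum); cognitive accuracy and speed test
scores genetically correlated with the externalizing factor; and phenotypes
whose genetic variance changes log-linearly with age while the cross-age
genetic correlation decays exponentially with age difference.

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from ._linalg import connected_blocks
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, kinship_from_pedigree, MISSING_PARENT

__all__ = [
    "SimConfig",
    "TraitParams",
    "SimulatedCohort",
    "sim_pedigrees",
    "sim_genotypes",
    "sim_phenotype_gxage",
    "sim_bivariate",
    "sim_items",
    "inject_missingness",
    "sim_cohort",
    "gxage_covariance",
]

FACTOR_NAMES = ["anxious_misery", "externalizing", "fear", "psychosis", "general"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class TraitParams:
    """Age-varying variance-component truth for one trait.

    sigma2_g0 / sigma2_e0 are the genetic and environmental variances at the
    reference age; gamma_g / gamma_e are per-year slopes on the log variances;
    lam (>= 0, per year) is the decay rate of the cross-age genetic
    correlation.  ref_age = None means the sample mean age.
    """

    sigma2_g0: float = 0.46
    sigma2_e0: float = 0.54
    gamma_g: float = -0.146
    gamma_e: float = 0.059
    lam: float = 0.027
    ref_age: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2_g0 < 0 or self.sigma2_e0 < 0:
            raise ConfigError("variances must be nonnegative")
        if self.lam < 0:
            raise ConfigError("lambda must be >= 0")


@dataclass
class SimConfig:
    """Full cohort-simulation configuration; defaults define the reference
    study conditions at desk scale."""

    n_families: int = 250
    children_per_family: object = ("poisson", 2.0)  # int, or ("poisson", mean)
    n_singletons: int = 500
    age_range: tuple[float, float] = (8.0, 21.0)
    # genotypes
    n_snps: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_corr: float = 0.8
    # externalizing trait truth (age-varying variance components)
    trait: TraitParams = field(default_factory=TraitParams)
    # bifactor truth: standardized loadings and marginal endorsement targets
    n_items: int = 112
    general_loading: float = 0.6
    specific_loading: float = 0.4
    endorsement_targets: dict = field(
        default_factory=lambda: {
            "anxious_misery": 0.15,
            "externalizing": 0.21,
            "fear": 0.16,
            "psychosis": 0.11,
        }
    )
    # static heritabilities of the remaining latent traits (unit variance)
    h2: dict = field(
        default_factory=lambda: {
            "anxious_misery": 0.09,
            "externalizing": 0.46,  # overridden by `trait` in sim_cohort
            "fear": 0.04,
            "psychosis": 0.00,
            "general": 0.21,
            "ability": 0.50,
            "speed": 0.30,
        }
    )
    # genetic correlation between externalizing and cognitive ability
    rho_g_ext_ability: float = -0.394
    # cognitive battery: n_tests accuracy + n_tests reaction-time columns
    n_tests: int = 14
    test_loading: float = 0.8
    missing_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.trait, dict):
            self.trait = TraitParams(**self.trait)
        if self.n_families < 0 or self.n_singletons < 0 or self.n_snps <= 0:
            raise ConfigError("counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf range must lie in (0, 0.5]")
        if not (0 <= self.ld_corr < 1):
            raise ConfigError("ld correlation must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing rate must be in [0, 1)")
        for k, v in self.endorsement_targets.items():
            if not (0 < v < 1):
                raise ConfigError(f"endorsement target for {k} must be in (0,1)")
        _ = _children_sampler(self.children_per_family)  # validate spec early

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        if isinstance(raw.get("children_per_family"), list):
            raw["children_per_family"] = tuple(raw["children_per_family"])
        return cls(**raw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _children_sampler(spec):
    """Return rng, size -> integer array of children counts."""
    if isinstance(spec, (int, np.integer)):
        if spec < 0:
            raise ConfigError("children count must be >= 0")
        return lambda rng, size: np.full(size, int(spec))
    if isinstance(spec, (tuple, list)) and len(spec) == 2 and spec[0] == "poisson":
        mean = float(spec[1])
        if mean < 0:
            raise ConfigError("poisson mean must be >= 0")
        return lambda rng, size: rng.poisson(mean, size)
    raise ConfigError(f"invalid children-per-family spec: {spec!r}")


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def sim_pedigrees(config: SimConfig, seed: int | None = None) -> Pedigree:
    """Nuclear families (two founder parents + children) plus singletons.

    Ages uniform on the configured range for everyone (the cohort is a
    cross-sectional age-structured sample, not a literal genealogy); sex
    Bernoulli(0.5) for children and singletons, parents are one of each.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    draw_children = _children_sampler(config.children_per_family)
    lo, hi = config.age_range

    rows = []
    kids = draw_children(rng, config.n_families)
    for f in range(config.n_families):
        fam = f"F{f:05d}"
        fa, mo = f"{fam}_P1", f"{fam}_P2"
        rows.append((fam, fa, MISSING_PARENT, MISSING_PARENT, 1))
        rows.append((fam, mo, MISSING_PARENT, MISSING_PARENT, 2))
        for c in range(kids[f]):
            rows.append((fam, f"{fam}_C{c + 1}", fa, mo, int(rng.integers(1, 3))))
    for s in range(config.n_singletons):
        fam = f"S{s:05d}"
        rows.append((fam, f"{fam}_I1", MISSING_PARENT, MISSING_PARENT,
                     int(rng.integers(1, 3))))

    t = pd.DataFrame(rows, columns=["family", "iid", "father", "mother", "sex"])
    t["age"] = rng.uniform(lo, hi, len(t))
    return Pedigree(t)


# ---------------------------------------------------------------------------
# genotypes: gene dropping with blockwise LD
# ---------------------------------------------------------------------------

def sim_genotypes(ped: Pedigree, config: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Gene-drop SNP dosages down the pedigree.

    Founder haplotypes are drawn per SNP from Hardy-Weinberg at a MAF uniform
    on the configured range; within an LD block (all SNPs of a block share one
    MAF) each haplotype copies the previous SNP's allele with probability
    ``ld_corr``, giving adjacent-allele correlation ~= ld_corr.  Children
    receive one randomly segregated allele per parent per SNP.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    m = config.n_snps
    block = max(1, config.ld_block_size)
    n_blocks = -(-m // block)
    block_maf = rng.uniform(*config.maf_range, n_blocks)
    maf = np.repeat(block_maf, block)[:m]
    block_start = np.zeros(m, dtype=bool)
    block_start[::block] = True

    founders = ped.is_founder()
    n = len(ped)
    n_f = int(founders.sum())

    # founder haplotypes with Markov copying inside blocks
    hap = np.empty((2 * n_f, m), dtype=np.uint8)
    fresh = rng.random((2 * n_f, m)) < maf[None, :]
    copy = rng.random((2 * n_f, m)) < config.ld_corr
    hap[:, 0] = fresh[:, 0]
    for j in range(1, m):
        if block_start[j]:
            hap[:, j] = fresh[:, j]
        else:
            hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh[:, j])

    pos = {iid: i for i, iid in enumerate(ped.ids)}
    hap_index = np.full(n, -1)
    hap_index[founders] = np.arange(n_f)

    dosage = np.empty((n, m), dtype=np.float32)
    dosage[founders] = (hap[0::2] + hap[1::2]).astype(np.float32)

    # transmitted haplotypes (per-SNP independent segregation, no crossover map)
    child_hap: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def gamete(parent_idx: int) -> np.ndarray:
        if hap_index[parent_idx] >= 0:
            h1 = hap[2 * hap_index[parent_idx]]
            h2 = hap[2 * hap_index[parent_idx] + 1]
        else:
            h1, h2 = child_hap[parent_idx]
        pick = rng.integers(0, 2, m).astype(np.uint8)
        return np.where(pick == 0, h1, h2)

    t = ped.table
    order = ped._topological_order()
    for i in order:
        if founders[i]:
            continue
        f, mo_ = pos[t["father"].iloc[i]], pos[t["mother"].iloc[i]]
        ga, gb = gamete(f), gamete(mo_)
        child_hap[i] = (ga, gb)
        dosage[i] = (ga + gb).astype(np.float32)

    snps = pd.DataFrame(
        {"snp": [f"snp{j}" for j in range(m)],
         "chrom": np.ones(m, dtype=int),
         "pos": np.arange(1, m + 1) * 1000,
         "freq": maf}
    )
    return GenotypeMatrix(ids=ped.ids.copy(), dosages=dosage.astype(float), snps=snps)


# ---------------------------------------------------------------------------
# age-varying variance-component phenotypes
# ---------------------------------------------------------------------------

def _sigma_g(ages, params: TraitParams, ref_age: float):
    return np.sqrt(params.sigma2_g0) * np.exp(0.5 * params.gamma_g * (ages - ref_age))


def _sigma_e(ages, params: TraitParams, ref_age: float):
    return np.sqrt(params.sigma2_e0) * np.exp(0.5 * params.gamma_e * (ages - ref_age))


def gxage_covariance(K: np.ndarray, ages: np.ndarray, params: TraitParams) -> np.ndarray:
    """Dense covariance Omega of the age-varying polygenic model:

    Omega_ij = K_ij * sig_g(a_i) * sig_g(a_j) * exp(-lam*|a_i-a_j|)
               + 1[i=j] * sig_e(a_i)^2

    with sig_g(a)^2 = sigma2_g0*exp(gamma_g*(a-abar)) and the environmental
    analogue.  PSD by construction: the exponential-decay kernel is a valid
    correlation matrix and Schur products of PSD matrices are PSD.
    """
    ages = np.asarray(ages, dtype=float)
    abar = params.ref_age if params.ref_age is not None else ages.mean()
    sg = _sigma_g(ages, params, abar)
    decay = np.exp(-params.lam * np.abs(ages[:, None] - ages[None, :]))
    omega = np.asarray(K) * np.outer(sg, sg) * decay
    omega[np.diag_indices_from(omega)] += _sigma_e(ages, params, abar) ** 2
    return omega


def sim_phenotype_gxage(
    K: np.ndarray,
    ages: np.ndarray,
    params: TraitParams | None = None,
    seed: int = 0,
    n_draws: int = 1,
) -> np.ndarray:
    """Draw traits from N(0, Omega) under the Gene x Age model (see
    :func:`gxage_covariance`); exploits the family-block structure of K."""
    params = params or TraitParams()
    K = np.asarray(K, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if K.shape[0] != len(ages):
        raise ValueError("ages must align with K")
    rng = np.random.default_rng(seed)
    y = np.empty((n_draws, K.shape[0]))
    abar = params.ref_age if params.ref_age is not None else ages.mean()
    pfixed = TraitParams(params.sigma2_g0, params.sigma2_e0, params.gamma_g,
                         params.gamma_e, params.lam, ref_age=abar)
    for ix in connected_blocks(K):
        omega = gxage_covariance(K[np.ix_(ix, ix)], ages[ix], pfixed)
        L = _chol_psd(omega)
        y[:, ix] = rng.standard_normal((n_draws, len(ix))) @ L.T
    return y[0] if n_draws == 1 else y


def _chol_psd(C: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    try:
        return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        if w.min() < -1e-8:
            raise RuntimeError("covariance not PSD beyond tolerance")
        return V * np.sqrt(np.clip(w, 0.0, None))


# ---------------------------------------------------------------------------
# bivariate polygenic draws
# ---------------------------------------------------------------------------

def sim_bivariate(
    K: np.ndarray,
    params: dict,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-variance traits from the bivariate polygenic model.

    ``params``: h2_1, h2_2 in [0,1]; rho_g, rho_e in [-1,1].  The genetic
    cross-covariance is rho_g*sqrt(h2_1*h2_2)*K, the environmental one
    rho_e*sqrt((1-h2_1)(1-h2_2))*I.
    """
    h1, h2_ = params["h2_1"], params["h2_2"]
    rg, re = params["rho_g"], params["rho_e"]
    if not (0 <= h1 <= 1 and 0 <= h2_ <= 1):
        raise ConfigError("heritabilities must be in [0,1]")
    if abs(rg) > 1 or abs(re) > 1:
        raise ConfigError("correlations must be in [-1,1]")
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    rng = np.random.default_rng(seed)
    y = np.empty((2, n))
    cg = rg * np.sqrt(h1 * h2_)
    ce = re * np.sqrt((1 - h1) * (1 - h2_))
    for ix in connected_blocks(K):
        b = len(ix)
        Kb = K[np.ix_(ix, ix)]
        Ib = np.eye(b)
        C = np.block([[h1 * Kb + (1 - h1) * Ib, cg * Kb + ce * Ib],
                      [cg * Kb + ce * Ib, h2_ * Kb + (1 - h2_) * Ib]])
        L = _chol_psd(C)
        z = rng.standard_normal(2 * b) @ L.T
        y[0, ix] = z[:b]
        y[1, ix] = z[b:]
    return y[0], y[1]


# ---------------------------------------------------------------------------
# binary symptom items
# ---------------------------------------------------------------------------

def sim_items(scores, model, seed: int = 0) -> pd.DataFrame:
    """Bernoulli item responses: P(y_ij = 1) = Phi(L_j . eta_i - tau_j) on the
    response (raw probit) scale of ``model`` (a psychometrics BifactorModel).
    """
    eta = np.asarray(scores, dtype=float)
    L, tau = model.raw_slopes(), model.raw_intercepts()
    if eta.shape[1] != L.shape[1]:
        raise ValueError("factor-score dimension does not match model loadings")
    rng = np.random.default_rng(seed)
    p = norm.cdf(eta @ L.T - tau[None, :])
    resp = (rng.random(p.shape) < p).astype(int)
    return pd.DataFrame(resp, columns=model.item_ids)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int = 0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Set entries missing completely at random at the given rate."""
    if not (0 <= rate < 1):
        raise ConfigError("rate must be in [0, 1)")
    out = table.copy()
    if rate == 0:
        return out
    cols = columns if columns is not None else [
        c for c in out.columns
        if out[c].dtype.kind == "f" and c not in ("age",)
    ]
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(cols))) < rate
    vals = out[cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[cols] = vals
    return out


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Everything a pipeline run consumes, plus the generating truth."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    kinship: np.ndarray           # expected relationship 2*Phi from pedigree
    true_scores: pd.DataFrame     # latent factor + cognitive-latent values
    items: pd.DataFrame           # binary symptom responses
    traits: pd.DataFrame          # iid, age, sex, cognitive columns (with NaN)
    model: object                 # generating BifactorModel
    config: SimConfig


def sim_cohort(config: SimConfig | None = None, seed: int | None = None,
               genotypes: bool = True) -> SimulatedCohort:
    """Simulate the full synthetic cohort.

    Latent traits (five psychopathology factors + cognitive ability and
    speed) are drawn jointly per family block: genetic covariance is the
    Kronecker-style product of the trait genetic-correlation matrix with the
    age-decayed kinship kernel, scaled by per-trait age-varying genetic SDs;
    environmental effects are independent across individuals.  Externalizing
    carries the configured Gene x Age truth; the other traits are static.
    """
    from .psychometrics import default_item_pattern, build_bifactor_truth

    config = config or SimConfig()
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    ped = sim_pedigrees(config, seed=seeds[0])
    geno = sim_genotypes(ped, config, seed=seeds[1]) if genotypes else None
    K, _ = kinship_from_pedigree(ped)
    ages = ped.ages
    abar = config.trait.ref_age if config.trait.ref_age is not None else ages.mean()

    traits = FACTOR_NAMES + ["ability", "speed"]
    T = len(traits)
    ext = traits.index("externalizing")
    abl = traits.index("ability")

    # per-trait age-varying genetic / environmental SD profiles
    sg = np.empty((T, len(ped)))
    se = np.empty((T, len(ped)))
    for t, name in enumerate(traits):
        if name == "externalizing":
            p = TraitParams(config.trait.sigma2_g0, config.trait.sigma2_e0,
                            config.trait.gamma_g, config.trait.gamma_e,
                            config.trait.lam, ref_age=abar)
        else:
            h2 = config.h2[name]
            p = TraitParams(h2, 1 - h2, 0.0, 0.0, 0.0, ref_age=abar)
        sg[t] = _sigma_g(ages, p, abar)
        se[t] = _sigma_e(ages, p, abar)

    Rg = np.eye(T)
    Rg[ext, abl] = Rg[abl, ext] = config.rho_g_ext_ability
    lam = config.trait.lam

    rng = np.random.default_rng(seeds[2])
    eta = np.empty((T, len(ped)))
    for ix in connected_blocks(K):
        b = len(ix)
        Kb = K[np.ix_(ix, ix)]
        decay = np.exp(-lam * np.abs(ages[ix][:, None] - ages[ix][None, :]))
        base = Kb * decay
        # genetic: (Rg kron base) scaled by diag(sg); environmental: diag
        Sg = sg[:, ix].reshape(T * b)
        C = np.kron(Rg, base) * np.outer(Sg, Sg)
        C[np.diag_indices_from(C)] += se[:, ix].reshape(T * b) ** 2
        z = rng.standard_normal(T * b) @ _chol_psd(C).T
        eta[:, ix] = z.reshape(T, b)

    true_scores = pd.DataFrame(eta.T, columns=traits)
    true_scores.insert(0, "iid", ped.ids)

    # symptom items from the five factors
    pattern = default_item_pattern(config.n_items)
    model = build_bifactor_truth(
        pattern,
        general=config.general_loading,
        specific=config.specific_loading,
        endorsement_targets=config.endorsement_targets,
    )
    factor_eta = true_scores[model.factor_names].to_numpy()
    items = sim_items(factor_eta, model, seed=seeds[3])
    items.insert(0, "iid", ped.ids)

    # cognitive battery: accuracy loads ability, reaction time loads slowness
    l = config.test_loading
    u = np.sqrt(1 - l * l)
    rng2 = np.random.default_rng(seeds[4])
    cog = {}
    for k in range(config.n_tests):
        cog[f"acc_{k + 1:02d}"] = l * eta[abl] + u * rng2.standard_normal(len(ped))
    slow = traits.index("speed")
    for k in range(config.n_tests):
        cog[f"rt_{k + 1:02d}"] = l * eta[slow] + u * rng2.standard_normal(len(ped))
    traits_df = pd.DataFrame({"iid": ped.ids, "age": ages, "sex": ped.sexes, **cog})
    cog_cols = [c for c in traits_df.columns if c.startswith(("acc_", "rt_"))]
    traits_df = inject_missingness(traits_df, config.missing_rate,
                                   seed=seeds[5], columns=cog_cols)

    return SimulatedCohort(
        pedigree=ped, genotypes=geno, kinship=K, true_scores=true_scores,
        items=items, traits=traits_df, model=model, config=config,
    )
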
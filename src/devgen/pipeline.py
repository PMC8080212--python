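"""End-to-end orchestration: simulate -> factor scores -> trait prep -> GRM
-> heritability screen -> genetic correlations -> Gene x Age -> report.

Bivariate and Gene x Age stages run only on traits that pass the
FDR-corrected heritability screen, mirroring the analysis workflow the
package implements.  Every run writes its artifacts plus a manifest of
content hashes; a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phenotypes import (build_covariates, chained_impute, eligibility_filter,
                         pca_composite)
from .psychometrics import BifactorEstimator
from .relatedness import empirical_grm, ld_prune, pedigree_grm, validate_grm, write_grm
from .simulate import SimConfig, sim_cohort
from .varcomp import (BivariateModel, GxAgeModel, PolygenicModel, bh_fdr,
                      inverse_normal, variance_by_age)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_report_tables"]

log = logging.getLogger("devgen")

FACTOR_TRAITS = ["anxious_misery", "externalizing", "fear", "psychosis", "general"]
COMPOSITE_TRAITS = ["g", "gs"]


@dataclass
class PipelineConfig:
    """Run configuration; everything downstream is derived from it."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "devgen_run"
    seed: int = 0
    fdr_q: float = 0.05
    ld_r2: float = 0.1
    ld_window: int = 50
    grm_source: str = "empirical"   # or 'pedigree'
    # |K_ij| below this are zeroed before model fitting (None = adaptive,
    # max(0.05, 4/sqrt(M)) for an M-SNP GRM): with desk-scale SNP counts the
    # sampling noise of unrelated pairs otherwise swamps the relatedness
    # signal that identifies the variance components
    grm_cutoff: float | None = None
    variant: str = "bifactor"
    n_starts: int = 3
    age_grid_step: float = 1.0
    write_genotypes: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if not (0 < self.fdr_q < 1):
            raise ValueError("FDR level q must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(d, default=_jsonable)), fh,
                           sort_keys=False)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, tuple):
        return list(o)
    return str(o)


@dataclass
class RunReport:
    """Stage counts, filter log, and the result tables."""

    counts: dict
    heritability: pd.DataFrame
    correlations: pd.DataFrame
    gxage: pd.DataFrame
    curves: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_report_tables(h2_fits: dict, biv_fits: dict, gx_fits: dict,
                       q: float = 0.05):
    """Assemble the heritability / correlation / Gene x Age tables with
    FDR flags computed per family of tests."""
    rows = []
    for trait, m in h2_fits.items():
        rows.append({
            "trait": trait, "n": m.n_, "h2": m.h2_, "h2_se": m.h2_se_,
            "p": m.lrt_h2_.p_value,
        })
    h2_tab = pd.DataFrame(rows, columns=["trait", "n", "h2", "h2_se", "p"])
    if len(h2_tab):
        rej, p_adj = bh_fdr(h2_tab["p"].to_numpy(), q=q)
        h2_tab["p_fdr"] = p_adj
        h2_tab["significant"] = rej

    rows = []
    for (t1, t2), m in biv_fits.items():
        rows.append({
            "trait1": t1, "trait2": t2, "rho_g": m.rho_g_,
            "rho_g_se": getattr(m, "se_", {}).get("rho_g", np.nan),
            "rho_e": m.rho_e_, "rho_p": m.rho_p_,
            "p_rho_g": m.lrt_rho_g_.p_value, "p_rho_e": m.lrt_rho_e_.p_value,
        })
    biv_tab = pd.DataFrame(rows, columns=["trait1", "trait2", "rho_g", "rho_g_se",
                                          "rho_e", "rho_p", "p_rho_g", "p_rho_e"])
    if len(biv_tab):
        rej, p_adj = bh_fdr(biv_tab["p_rho_g"].to_numpy(), q=q)
        biv_tab["p_rho_g_fdr"] = p_adj
        biv_tab["significant"] = rej

    rows = []
    for trait, m in gx_fits.items():
        rows.append({
            "trait": trait, "gamma_g": m.gamma_g_, "gamma_e": m.gamma_e_,
            "lambda": m.lambda_, "p_gamma_g": m.lrt_gamma_g_.p_value,
            "p_gamma_e": m.lrt_gamma_e_.p_value,
            "p_lambda": m.lrt_lambda_.p_value,
        })
    gx_tab = pd.DataFrame(rows, columns=["trait", "gamma_g", "gamma_e", "lambda",
                                         "p_gamma_g", "p_gamma_e", "p_lambda"])
    if len(gx_tab):
        pcols = gx_tab[["p_gamma_g", "p_gamma_e", "p_lambda"]].to_numpy().ravel()
        rej, p_adj = bh_fdr(pcols, q=q)
        gx_tab[["p_gamma_g_fdr", "p_gamma_e_fdr", "p_lambda_fdr"]] = \
            p_adj.reshape(-1, 3)
    return h2_tab, biv_tab, gx_tab


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(levelname)s %(message)s")
    counts: dict = {}
    written: list[Path] = []

    # -- stage 1: simulate -------------------------------------------------
    sim_cfg = config.sim
    cohort = sim_cohort(sim_cfg, seed=config.seed)
    n = len(cohort.pedigree)
    counts["simulated_individuals"] = n
    ped_t = cohort.pedigree.table
    counts["families"] = int(ped_t.loc[ped_t["father"] != "0", "family"].nunique())
    log.info("simulated cohort: %d individuals, %d items, %d SNPs",
             n, cohort.items.shape[1] - 1, cohort.genotypes.n_snps)
    cohort.pedigree.to_fam(out / "pedigree.fam")
    written.append(out / "pedigree.fam")
    cohort.items.to_csv(out / "items.tsv", sep="\t", index=False)
    written.append(out / "items.tsv")
    cohort.traits.to_csv(out / "traits_raw.tsv", sep="\t", index=False,
                         float_format="%.10g")
    written.append(out / "traits_raw.tsv")
    if config.write_genotypes:
        cohort.genotypes.to_raw(out / "genotypes.raw")
        written.append(out / "genotypes.raw")
    sim_cfg.to_yaml(out / "sim_config.yaml")
    written.append(out / "sim_config.yaml")

    # -- stage 2: factor scores -------------------------------------------
    est = BifactorEstimator(variant=config.variant, n_starts=config.n_starts,
                            seed=config.seed)
    est.fit(cohort.items)
    scores = est.transform(cohort.items)
    log.info("factor model fitted: discrepancy %.4f", est.discrepancy_)
    scores.to_csv(out / "factor_scores.tsv", sep="\t", index=False,
                  float_format="%.10g")
    written.append(out / "factor_scores.tsv")
    est.model_.to_json(out / "factor_model.json")
    written.append(out / "factor_model.json")

    # -- stage 3: trait prep ----------------------------------------------
    cog_cols = [c for c in cohort.traits.columns if c.startswith(("acc_", "rt_"))]
    filtered, removed = eligibility_filter(cohort.traits, cog_cols, 0.5)
    counts["eligibility_removed"] = len(removed)
    counts["eligible"] = len(filtered)
    imputed = chained_impute(filtered, cog_cols, seed=config.seed + 11)
    acc_cols = [c for c in cog_cols if c.startswith("acc_")]
    rt_cols = [c for c in cog_cols if c.startswith("rt_")]
    imputed = imputed.copy()
    imputed["g"] = pca_composite(imputed, acc_cols, acc_cols[0]).to_numpy()
    imputed["gs"] = pca_composite(imputed, rt_cols, rt_cols[0]).to_numpy()
    table = imputed.merge(scores, on="iid", how="left")
    table.to_csv(out / "traits_prepared.tsv", sep="\t", index=False,
                 float_format="%.10g")
    written.append(out / "traits_prepared.tsv")

    # -- stage 4: GRM ------------------------------------------------------
    if config.grm_source == "pedigree":
        K = pedigree_grm(cohort.pedigree)
    else:
        pruned = ld_prune(cohort.genotypes, config.ld_r2, config.ld_window)
        counts["snps_after_pruning"] = pruned.n_snps
        log.info("LD pruning: %d -> %d SNPs", cohort.genotypes.n_snps, pruned.n_snps)
        K = empirical_grm(pruned)
    report = validate_grm(K)
    if not report.passed:
        log.warning("GRM checks failed: %s", report.checks)
    counts["grm_individuals"] = K.n
    write_grm(K, str(out / "grm"), dialect="gcta")
    written += [out / "grm.grm", out / "grm.grm.id"]

    # align trait table with the GRM; suppress unrelated-pair noise
    K = K.subset(table["iid"].to_numpy())
    if config.grm_source == "empirical":
        cutoff = config.grm_cutoff
        if cutoff is None:
            cutoff = max(0.05, 4.0 / np.sqrt(K.n_snps or 1))
        counts["grm_cutoff"] = round(float(cutoff), 4)
        K = K.sparsified(cutoff)
    ages = table["age"].to_numpy(dtype=float)
    X = build_covariates(ages, table["sex"].to_numpy()).to_numpy()

    # -- stage 5: heritability screen -------------------------------------
    traits = FACTOR_TRAITS + COMPOSITE_TRAITS
    h2_fits = {}
    for t in traits:
        y = inverse_normal(table[t].to_numpy(dtype=float))
        h2_fits[t] = PolygenicModel().fit(y, K.values, X)
        log.info("h2[%s] = %.3f (p=%.3g)", t, h2_fits[t].h2_,
                 h2_fits[t].lrt_h2_.p_value)
    counts["varcomp_individuals"] = h2_fits[traits[0]].n_

    h2_tab_tmp, _, _ = make_report_tables(h2_fits, {}, {}, q=config.fdr_q)
    passing = list(h2_tab_tmp.loc[h2_tab_tmp["significant"], "trait"])
    counts["h2_fdr_passing"] = len(passing)
    log.info("FDR-passing traits: %s", passing)

    # -- stage 6: genetic correlations (factor x cognition, both passing) --
    biv_fits = {}
    for t1 in [t for t in passing if t in FACTOR_TRAITS]:
        for t2 in [t for t in passing if t in COMPOSITE_TRAITS]:
            y1 = inverse_normal(table[t1].to_numpy(dtype=float))
            y2 = inverse_normal(table[t2].to_numpy(dtype=float))
            biv_fits[(t1, t2)] = BivariateModel(
                n_starts=config.n_starts, seed=config.seed).fit(y1, y2, K.values, X)
            log.info("rho_g[%s,%s] = %.3f", t1, t2, biv_fits[(t1, t2)].rho_g_)

    # -- stage 7: Gene x Age on FDR-passing traits -------------------------
    gx_fits = {}
    for t in passing:
        y = inverse_normal(table[t].to_numpy(dtype=float))
        gx_fits[t] = GxAgeModel(n_starts=config.n_starts, seed=config.seed).fit(
            y, K.values, ages, X)
        log.info("gxage[%s]: gamma_g=%.3f gamma_e=%.3f lambda=%.3f", t,
                 gx_fits[t].gamma_g_, gx_fits[t].gamma_e_, gx_fits[t].lambda_)

    # -- stage 8: report ---------------------------------------------------
    h2_tab, biv_tab, gx_tab = make_report_tables(h2_fits, biv_fits, gx_fits,
                                                 q=config.fdr_q)
    lo, hi = sim_cfg.age_range
    grid = np.arange(lo, hi + 1e-9, config.age_grid_step)
    curve_frames = []
    for t, m in gx_fits.items():
        c = variance_by_age(m, grid)
        c.insert(0, "trait", t)
        curve_frames.append(c)
    curves = (pd.concat(curve_frames, ignore_index=True) if curve_frames
              else pd.DataFrame(columns=["trait", "age", "sigma2_g", "sigma2_e", "h2"]))

    for name, tab in [("heritability.tsv", h2_tab), ("correlations.tsv", biv_tab),
                      ("gxage.tsv", gx_tab), ("curves.tsv", curves)]:
        tab.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        written.append(out / name)

    manifest = {p.name: _sha256(p) for p in written}
    manifest_payload = {"seed": config.seed, "files": manifest}
    (out / "manifest.json").write_text(json.dumps(manifest_payload, indent=1,
                                                  sort_keys=True))

    return RunReport(counts=counts, heritability=h2_tab, correlations=biv_tab,
                     gxage=gx_tab, curves=curves,
                     manifest=manifest_payload)
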
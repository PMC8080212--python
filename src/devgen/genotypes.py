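"""Dosage genotype container and PLINK .raw-style additive-coding I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive dosages in {0, 1, 2}, NaN for missing.

    ``snps`` carries one record per marker (id, chromosome, position,
    allele frequency); frequencies are computed from the sample when absent.
    """

    ids: np.ndarray
    dosages: np.ndarray  # float array, n x m, values 0/1/2 or NaN
    snps: pd.DataFrame = field(default=None)  # columns: snp, chrom, pos, freq

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.ids):
            raise ValueError("dosage matrix must be n_individuals x n_snps")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if self.snps is None:
            m = self.dosages.shape[1]
            self.snps = pd.DataFrame(
                {"snp": [f"snp{j}" for j in range(m)],
                 "chrom": np.ones(m, dtype=int),
                 "pos": np.arange(1, m + 1) * 1000}
            )
        if "freq" not in self.snps.columns:
            self.snps = self.snps.assign(freq=self.allele_frequencies())

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency, column mean / 2 over observed."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            ids=self.ids,
            dosages=self.dosages[:, keep],
            snps=self.snps.iloc[np.atleast_1d(keep)].reset_index(drop=True),
        )

    # -- I/O: .raw additive dialect (header = IID + SNP ids) ---------------
    def to_raw(self, path) -> None:
        df = pd.DataFrame(self.dosages, columns=self.snps["snp"])
        df.insert(0, "IID", self.ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")

    @classmethod
    def from_raw(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        if "IID" not in df.columns:
            raise ValueError("dosage table must have an IID column")
        ids = df["IID"].astype(str).to_numpy()
        snp_cols = [c for c in df.columns if c != "IID"]
        m = len(snp_cols)
        snps = pd.DataFrame(
            {"snp": snp_cols, "chrom": np.ones(m, dtype=int),
             "pos": np.arange(1, m + 1) * 1000}
        )
        return cls(ids=ids, dosages=df[snp_cols].to_numpy(dtype=float), snps=snps)
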
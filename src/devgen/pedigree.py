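"""Pedigrees: construction, validation, expected kinship, and .fam-style I/O.

A pedigree here is a cross-sectional cohort of nuclear families (two founder
parents plus children) and unrelated singletons, each individual carrying sex
and an age in years.  Related pairs observed at different ages are what make
age-varying genetic models identifiable in a cross-sectional design, so the
pedigree is the backbone of every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "kinship_from_pedigree"]

_FAM_COLUMNS = ["family", "iid", "father", "mother", "sex", "age"]
MISSING_PARENT = "0"


@dataclass
class Pedigree:
    """Cohort table with parent links, sex (1=male, 2=female) and age in years.

    ``table`` has columns ``family, iid, father, mother, sex, age``; absent
    parents are coded ``"0"``.  Founders have both parents absent.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _FAM_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.table["iid"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    @property
    def sexes(self) -> np.ndarray:
        return self.table["sex"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.table)

    def is_founder(self) -> np.ndarray:
        t = self.table
        return ((t["father"] == MISSING_PARENT) & (t["mother"] == MISSING_PARENT)).to_numpy()

    def validate(self) -> None:
        t = self.table
        ids = t["iid"]
        if ids.duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for col in ("father", "mother"):
            refs = t[col][t[col] != MISSING_PARENT]
            unknown = set(refs) - known
            if unknown:
                raise ValueError(f"{col} ids not present in pedigree: {sorted(unknown)[:5]}")
        half = (t["father"] == MISSING_PARENT) ^ (t["mother"] == MISSING_PARENT)
        if half.any():
            raise ValueError("individuals must have both parents present or both absent")
        self._topological_order()  # raises on cycles

    def _topological_order(self) -> np.ndarray:
        """Indices ordered founders-first; raises ValueError on a cyclic pedigree."""
        t = self.table
        pos = {iid: i for i, iid in enumerate(t["iid"])}
        parents = [
            [pos[p] for p in (fa, mo) if p != MISSING_PARENT]
            for fa, mo in zip(t["father"], t["mother"])
        ]
        order: list[int] = []
        state = np.zeros(len(t), dtype=int)  # 0 unvisited, 1 in-progress, 2 done

        for start in range(len(t)):
            if state[start]:
                continue
            stack = [(start, iter(parents[start]))]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                for p in it:
                    if state[p] == 1:
                        raise ValueError("cyclic parent links in pedigree")
                    if state[p] == 0:
                        state[p] = 1
                        stack.append((p, iter(parents[p])))
                        break
                else:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        return np.asarray(order)

    # -- I/O --------------------------------------------------------------
    def to_fam(self, path) -> None:
        """Write six-column whitespace-delimited .fam-style text (age in the
        phenotype slot)."""
        self.table[_FAM_COLUMNS].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_fam(cls, path) -> "Pedigree":
        t = pd.read_csv(
            path, sep=r"\s+", header=None, names=_FAM_COLUMNS,
            dtype={"family": str, "iid": str, "father": str, "mother": str},
        )
        return cls(t)


def kinship_from_pedigree(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Numerator relationship matrix A = 2*Phi from pedigree structure.

    Uses the standard recursion: for individual i with parents (f, m),
    ``A[i, j] = (A[f, j] + A[m, j]) / 2`` for prior j and
    ``A[i, i] = 1 + A[f, m] / 2`` (1 + inbreeding coefficient).

    Returns ``(A, ids)`` with rows in the pedigree's own order.
    """
    t = ped.table
    n = len(t)
    order = ped._topological_order()
    pos = {iid: i for i, iid in enumerate(t["iid"])}
    fa = np.array([pos.get(p, -1) for p in t["father"]])
    mo = np.array([pos.get(p, -1) for p in t["mother"]])

    A = np.zeros((n, n))
    for k, i in enumerate(order):
        f, m = fa[i], mo[i]
        if f < 0:  # founder: non-inbred, unrelated to anyone processed before
            A[i, i] = 1.0
            continue
        prior = order[:k]
        A[i, prior] = A[prior, i] = 0.5 * (A[f, prior] + A[m, prior])
        A[i, i] = 1.0 + 0.5 * A[f, m]
    return A, ped.ids.copy()
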
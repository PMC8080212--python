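import numpy as np
import pandas as pd
import pytest

from devgen.pedigree import Pedigree
from devgen.simulate import SimConfig, sim_pedigrees


@pytest.fixture
def three_gen_pedigree() -> Pedigree:
    """Three generations: grandparents -> parents -> children, plus an
    in-marrying founder; exercises recursion depth and half relationships."""
    rows = [
        # family, iid, father, mother, sex, age
        ("A", "gf", "0", "0", 1, 20.0),
        ("A", "gm", "0", "0", 2, 19.0),
        ("A", "fa", "gf", "gm", 1, 15.0),
        ("A", "un", "gf", "gm", 1, 14.0),     # uncle
        ("A", "mo", "0", "0", 2, 16.0),       # in-marrying founder
        ("A", "c1", "fa", "mo", 1, 9.0),
        ("A", "c2", "fa", "mo", 2, 12.0),
    ]
    return Pedigree(pd.DataFrame(
        rows, columns=["family", "iid", "father", "mother", "sex", "age"]))


@pytest.fixture(scope="session")
def sib_quad_cohort():
    """300 families of two parents + two children, plus 800 singletons
    (N = 2,000), with pedigree kinship."""
    from devgen.pedigree import kinship_from_pedigree

    cfg = SimConfig(n_families=300, children_per_family=2, n_singletons=800,
                    seed=42)
    ped = sim_pedigrees(cfg, seed=42)
    K, _ = kinship_from_pedigree(ped)
    return ped, K


@pytest.fixture(scope="session")
def toy_varcomp():
    """N = 6 toy: hand-specified kinship, ages, covariates, trait."""
    K = np.array([
        [1.0, 0.5, 0.5, 0.0, 0.0, 0.0],
        [0.5, 1.0, 0.25, 0.0, 0.0, 0.0],
        [0.5, 0.25, 1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0, 0.5, 0.0],
        [0.0, 0.0, 0.0, 0.5, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ])
    ages = np.array([8.0, 9.0, 12.0, 15.0, 18.0, 21.0])
    y = np.array([0.3, -1.2, 0.5, 1.1, -0.4, 0.9])
    X = np.column_stack([np.ones(6), ages - ages.mean()])
    return y, K, ages, X
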
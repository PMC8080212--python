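"""Internal helpers for block-structured covariance work.

Relatedness matrices from family cohorts are block diagonal up to ordering:
each family is a connected component of nonzero off-diagonals, singletons are
1x1 blocks.  Likelihood evaluation and multivariate-normal sampling both
exploit this by batching equally-sized blocks through LAPACK.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["connected_blocks", "group_blocks_by_size", "sample_blockwise_mvn"]


def connected_blocks(K: np.ndarray, tol: float = 1e-9) -> list[np.ndarray]:
    """Index sets of the connected components of ``|K| > tol`` off-diagonal.

    A dense matrix with no exact zeros yields a single component, so callers
    degrade gracefully to the dense case.
    """
    K = np.asarray(K)
    n = K.shape[0]
    mask = np.abs(K) > tol
    np.fill_diagonal(mask, False)
    ncomp, labels = connected_components(csr_matrix(mask), directed=False)
    out: list[np.ndarray] = [[] for _ in range(ncomp)]
    for i, lab in enumerate(labels):
        out[lab].append(i)
    return [np.asarray(ix, dtype=np.intp) for ix in out]


def group_blocks_by_size(blocks: list[np.ndarray]) -> dict[int, np.ndarray]:
    """Map block size b -> (n_blocks, b) array of index rows, for batched ops."""
    by_size: dict[int, list[np.ndarray]] = {}
    for ix in blocks:
        by_size.setdefault(len(ix), []).append(ix)
    return {b: np.vstack(rows) for b, rows in by_size.items()}


def sample_blockwise_mvn(
    cov_for_block,
    blocks: list[np.ndarray],
    n_total: int,
    rng: np.random.Generator,
    n_draws: int = 1,
    jitter: float = 1e-10,
) -> np.ndarray:
    """Draw from N(0, Omega) where Omega is block diagonal over ``blocks``.

    ``cov_for_block(ix)`` returns the dense covariance of the individuals in
    index set ``ix`` (size b x b, or k*b x k*b for stacked multi-trait blocks,
    in which case ``n_total`` counts stacked entries).  Returns shape
    ``(n_draws, n_total)``.
    """
    y = np.empty((n_draws, n_total))
    for ix in blocks:
        C = np.atleast_2d(np.asarray(cov_for_block(ix), dtype=float))
        m = C.shape[0]
        try:
            L = np.linalg.cholesky(C + jitter * np.eye(m))
        except np.linalg.LinAlgError:
            # fall back through eigenvalue clipping; Omega is PSD by
            # construction, so this only absorbs roundoff
            w, V = np.linalg.eigh(C)
            L = V * np.sqrt(np.clip(w, 0.0, None))
        z = rng.standard_normal((n_draws, m))
        if m == len(ix):
            y[:, ix] = z @ L.T
        else:  # stacked multi-trait block: caller supplies global positions
            raise ValueError("stacked blocks need explicit global positions")
    return y
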
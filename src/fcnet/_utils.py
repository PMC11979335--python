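"""Shared numerical helpers: seeding, edge vectorization, SPD repair."""
from __future__ import annotations

import numpy as np

__all__ = [
    "rng_from",
    "child_seed",
    "triu_pairs",
    "vectorize_matrix",
    "unvectorize_matrix",
    "nearest_spd_correlation",
]


def rng_from(master_seed: int, *stream: int) -> np.random.Generator:
    """Derive an independent Generator from a master seed and a stream key.

    All randomness in the package flows through one master seed; sub-streams
    (per subject, per permutation block, per stage) are spawned with integer
    keys so results are reproducible and order-independent.
    """
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *(int(s) for s in stream)])
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *stream: int) -> int:
    """A 31-bit integer seed derived from (master_seed, stream)."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *(int(s) for s in stream)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def triu_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle index pairs (i < j), the edge vectorization order."""
    return np.triu_indices(n, k=1)


def vectorize_matrix(mat: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix to its upper triangle (row-major, i < j)."""
    i, j = triu_pairs(mat.shape[0])
    return np.asarray(mat)[i, j]


def unvectorize_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_matrix`; diagonal is zero."""
    out = np.zeros((n, n), dtype=np.asarray(vec).dtype)
    i, j = triu_pairs(n)
    out[i, j] = vec
    out[j, i] = vec
    return out


def nearest_spd_correlation(
    mat: np.ndarray, eig_floor: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Project a symmetric matrix to a nearby SPD correlation matrix.

    Alternates eigenvalue clipping (at ``eig_floor``) with re-normalization to
    unit diagonal until the result is positive definite.  Raises
    ``np.linalg.LinAlgError`` if the iteration fails to produce an SPD matrix.
    """
    m = np.asarray(mat, dtype=float)
    m = (m + m.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(m)
        if w[0] > 0 and np.allclose(np.diag(m), 1.0, atol=1e-12):
            return m
        w = np.clip(w, eig_floor, None)
        m = (v * w) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 1.0)
    w = np.linalg.eigvalsh(m)
    if w[0] <= 0:
        raise np.linalg.LinAlgError(
            f"SPD projection failed: smallest eigenvalue {w[0]:.3e} after {max_iter} iterations"
        )
    return m
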
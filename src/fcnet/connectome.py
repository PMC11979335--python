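"""Functional-connectivity matrices and density-thresholded binary networks.

The per-subject connectome is the Fisher-z transformed Pearson correlation
matrix of the ROI time series (zero diagonal, symmetric).  Binary undirected
networks are obtained by *density* (sparsity) thresholding: at density D the
top round(D * N(N-1)/2) edges by absolute connectivity are kept, so every
subject's network has the same number of edges and topology is comparable
across subjects.  The admissible density range is the sub-grid where (i) every
subject's network is small-world (sigma > 1.1) and (ii) the mean degree
exceeds 2 ln N.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import triu_pairs, vectorize_matrix
from .cohort import TimeSeriesData

__all__ = [
    "FCMatrix",
    "BinaryNetwork",
    "DensityGrid",
    "DensityRangeError",
    "compute_fc",
    "binarize_at_density",
    "edge_index",
    "stack_fc",
    "validate_density_range",
]


@dataclass
class FCMatrix:
    """N x N Fisher-z connectivity matrix for one subject."""

    subject_id: str
    values: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("FC matrix contains non-finite entries")
        if np.any(np.diag(v) != 0):
            raise ValueError("FC matrix diagonal must be exactly 0")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary adjacency at a fixed density."""

    adjacency: np.ndarray
    density: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not (0 < self.density < 1):
            raise ValueError(f"density must lie in (0, 1), got {self.density}")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be 0")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


@dataclass(frozen=True)
class DensityGrid:
    """Ordered density (sparsity) grid: d_min, d_min + step, ..., d_max."""

    d_min: float = 0.10
    d_max: float = 0.50
    step: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.d_min <= self.d_max < 1):
            raise ValueError("need 0 < d_min <= d_max < 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.step)) + 1
        return np.round(self.d_min + self.step * np.arange(n), 10)


class DensityRangeError(ValueError):
    """No density on the grid satisfies the admissibility criteria."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message)
        self.diagnostics = diagnostics


def compute_fc(ts: TimeSeriesData, on_perfect: str = "error") -> FCMatrix:
    """Pearson correlation between every region pair, Fisher-z transformed.

    Parameters
    ----------
    ts : TimeSeriesData
    on_perfect : {"error", "clip"}
        Distinct noisy series never correlate at exactly |r| = 1, where the
        Fisher z-transform diverges; if it does arise, either fail (default)
        or clip |r| to 1 - 1e-12 before the transform.
    """
    x = ts.data
    if x.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to estimate correlations")
    sd = x.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [ts.region_labels[i] for i in constant]
        raise ValueError(f"constant time series for region(s) {names}; correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        if on_perfect == "clip":
            r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
        else:
            i, j = np.argwhere((np.abs(r) >= 1.0) & off)[0]
            raise ValueError(
                f"perfect correlation between regions {ts.region_labels[i]!r} and "
                f"{ts.region_labels[j]!r}; Fisher z undefined (set on_perfect='clip' to clip)"
            )
    z = np.arctanh(np.where(off, r, 0.0))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(subject_id=ts.subject_id, values=z, region_labels=list(ts.region_labels))


def _ranked_edges(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges ordered by |value| descending, ties by (i, j)."""
    i, j = triu_pairs(values.shape[0])
    absval = np.abs(values[i, j])
    # np.lexsort: last key is primary
    order = np.lexsort((j, i, -absval))
    return i[order], j[order], absval[order]


def binarize_at_density(fc: FCMatrix, d: float) -> BinaryNetwork:
    """Keep the strongest |z| edges so the network has density ``d``.

    Edge count = round(d * N(N-1)/2); ranking uses absolute connectivity
    (negative and positive edges treated alike), with a deterministic
    tie-break by region-pair order.
    """
    if not (0 < d < 1):
        raise ValueError(f"density must lie in (0, 1), got {d}")
    n = fc.n_regions
    m = n * (n - 1) // 2
    k = int(round(d * m))
    if k == 0:
        raise ValueError(f"density {d} keeps 0 of {m} edges")
    ri, rj, _ = _ranked_edges(fc.values)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ri[:k], rj[:k]] = 1
    adj[rj[:k], ri[:k]] = 1
    return BinaryNetwork(adjacency=adj, density=d, subject_id=fc.subject_id)


def edge_index(region_labels: list[str]) -> pd.DataFrame:
    """Mapping from vectorized edge position to region pair (upper triangle,
    row-major, 0-based)."""
    n = len(region_labels)
    i, j = triu_pairs(n)
    return pd.DataFrame(
        {
            "edge": np.arange(i.size),
            "i": i,
            "j": j,
            "region_i": [region_labels[a] for a in i],
            "region_j": [region_labels[b] for b in j],
        }
    )


def stack_fc(fcs: list[FCMatrix]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack subjects' FC matrices into a subjects x edges array plus its
    edge index (the vectorization contract for NBS and classification)."""
    if not fcs:
        raise ValueError("no FC matrices given")
    labels = fcs[0].region_labels
    for fc in fcs:
        if fc.region_labels != labels:
            raise ValueError(f"subject {fc.subject_id!r} has mismatched region labels")
    stack = np.vstack([vectorize_matrix(fc.values) for fc in fcs])
    return stack, edge_index(labels)


def validate_density_range(
    sigma: np.ndarray | pd.DataFrame,
    grid: DensityGrid,
    n_nodes: int,
    sw_threshold: float = 1.1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Admissible contiguous sub-grid of densities.

    A density is admissible when (i) every subject's small-world index sigma
    exceeds ``sw_threshold`` and (ii) the mean degree d*(N-1) exceeds
    2 ln N.  Returns the longest contiguous admissible run (ties: the
    lower-density run) and a per-density diagnostics table; raises
    :class:`DensityRangeError` when no density qualifies.

    Parameters
    ----------
    sigma : array (n_subjects, n_densities)
        Small-world index per subject per grid density.
    """
    sig = np.asarray(sigma, dtype=float)
    densities = grid.values
    if sig.ndim != 2 or sig.shape[1] != densities.size:
        raise ValueError(
            f"sigma must be (n_subjects, {densities.size}), got shape {sig.shape}"
        )
    mean_degree = densities * (n_nodes - 1)
    degree_ok = mean_degree > 2 * np.log(n_nodes)
    min_sigma = sig.min(axis=0)
    sw_ok = min_sigma > sw_threshold
    ok = degree_ok & sw_ok
    diag = pd.DataFrame(
        {
            "density": densities,
            "mean_degree": mean_degree,
            "degree_ok": degree_ok,
            "min_sigma": min_sigma,
            "smallworld_ok": sw_ok,
            "admissible": ok,
        }
    )
    if not ok.any():
        raise DensityRangeError(
            "no density satisfies both the small-world (sigma > "
            f"{sw_threshold}) and mean-degree (> 2 ln {n_nodes} = "
            f"{2 * np.log(n_nodes):.3f}) criteria",
            diag,
        )
    # longest contiguous run of True; first run wins ties
    best_start, best_len, start = 0, 0, None
    for idx, flag in enumerate(ok.tolist() + [False]):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            if idx - start > best_len:
                best_start, best_len = start, idx - start
            start = None
    return densities[best_start : best_start + best_len], diag
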
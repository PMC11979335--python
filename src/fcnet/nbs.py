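"""Network-based statistic (NBS): component-level permutation FWER inference.

Edge-wise group differences in Fisher-z connectivity are tested with a
covariate-adjusted OLS contrast; edges whose one-sided t exceeds a primary
threshold t0 are kept and their connected components extracted.  Each
observed component's family-wise-error-corrected p-value is the permutation
probability that the *maximal* null component extent (edge count) reaches the
observed extent.  Nuisance covariates are handled with Freedman-Lane residual
permutation (permute reduced-model residuals, refit the full model); plain
group-label permutation is available for designs without covariates.

Usage follows the model/results idiom::

    model = NetworkBasedStatistic(fc_stack, design, edge_pairs)
    result = model.fit(t0=3.5, n_perm=10000, seed=0)
    print(result.summary())
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import rng_from

__all__ = [
    "Component",
    "NBSResult",
    "NetworkBasedStatistic",
    "edgewise_stats",
    "suprathreshold_components",
    "permutation_test",
    "CONTRASTS",
]

#: one-sided contrasts; the sign multiplies the group (patient = 1) t statistic
CONTRASTS = {"patient_lt_control": -1.0, "patient_gt_control": 1.0}


@dataclass(frozen=True)
class Component:
    """A connected suprathreshold subnetwork."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    fwer_p: float | None = None

    @property
    def extent(self) -> int:
        return len(self.edges)

    def __post_init__(self) -> None:
        if len(self.nodes) > self.extent + 1:
            raise ValueError("component has more nodes than edges + 1; not connected")


def _design_matrix(design: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(design, pd.DataFrame):
        if "group" not in design.columns:
            raise ValueError("design must contain a 'group' column")
        return design.to_numpy(dtype=float), list(design.columns).index("group")
    X = np.asarray(design, dtype=float)
    return X, 1  # convention: column 1 is the group indicator


def _ols_t(X: np.ndarray, Y: np.ndarray, col: int, xtx_inv: np.ndarray | None = None) -> np.ndarray:
    """t statistic of coefficient ``col`` for every column of Y (vectorized OLS)."""
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than design columns ({p})")
    if xtx_inv is None:
        xtx = X.T @ X
        if np.linalg.matrix_rank(xtx) < p:
            raise ValueError("design matrix is rank deficient")
        xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    # an exactly-fitted edge (e.g. constant across subjects) leaves only
    # floating-point noise in the residuals; its statistic is 0, not noise/noise
    scale = (Y**2).mean(axis=0)
    degenerate = sigma2 <= 1e-24 * np.maximum(scale, 1e-300)
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where((se > 0) & ~degenerate, beta[col] / se, 0.0)
    return t


def edgewise_stats(
    fc_stack: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    contrast: str = "patient_lt_control",
) -> np.ndarray:
    """One-sided edge-wise t map: OLS of each edge's Fisher-z values on the
    design; positive values support the stated contrast direction."""
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(CONTRASTS)}, got {contrast!r}")
    Y = np.asarray(fc_stack, dtype=float)
    X, gi = _design_matrix(design)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"fc_stack has {Y.shape[0]} subjects but design has {X.shape[0]} rows"
        )
    g = X[:, gi]
    if (g == g[0]).all() or min((g == 1).sum(), (g != 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    return CONTRASTS[contrast] * _ols_t(X, Y, gi)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def suprathreshold_components(
    stats: np.ndarray,
    edge_pairs: np.ndarray,
    t0: float,
) -> list[Component]:
    """Connected components of the edges with statistic > t0, sorted by
    extent descending (union-find over kept edges)."""
    if t0 <= 0:
        raise ValueError(f"primary threshold t0 must be > 0, got {t0}")
    stats = np.asarray(stats, dtype=float)
    pairs = np.asarray(edge_pairs)
    keep = np.flatnonzero(stats > t0)
    if keep.size == 0:
        return []
    kept_pairs = pairs[keep]
    nodes = np.unique(kept_pairs)
    node_pos = {int(v): k for k, v in enumerate(nodes)}
    uf = _UnionFind(len(nodes))
    for i, j in kept_pairs:
        uf.union(node_pos[int(i)], node_pos[int(j)])
    groups: dict[int, list[tuple[int, int]]] = {}
    for i, j in kept_pairs:
        root = uf.find(node_pos[int(i)])
        groups.setdefault(root, []).append((int(i), int(j)))
    comps = []
    for edges in groups.values():
        cnodes = tuple(sorted({v for e in edges for v in e}))
        comps.append(Component(nodes=cnodes, edges=tuple(sorted(edges))))
    comps.sort(key=lambda c: (-c.extent, c.nodes))
    return comps


def _max_extent(stats: np.ndarray, pairs: np.ndarray, t0: float) -> int:
    comps = suprathreshold_components(stats, pairs, t0)
    return comps[0].extent if comps else 0


@dataclass
class NBSResult:
    """Results of an NBS fit: observed components with FWER p-values and the
    permutation null distribution of maximal component extents."""

    components: list[Component]
    null_max_extents: np.ndarray
    t0: float
    n_perm: int
    seed: int
    contrast: str
    edge_stats: np.ndarray = field(repr=False)
    edge_pairs: np.ndarray = field(repr=False)

    @property
    def n_significant(self) -> int:
        return sum(1 for c in self.components if c.fwer_p is not None and c.fwer_p < 0.05)

    def significant_components(self, alpha: float = 0.05) -> list[Component]:
        return [c for c in self.components if c.fwer_p is not None and c.fwer_p < alpha]

    def component_table(self, region_labels: list[str] | None = None) -> pd.DataFrame:
        """Edge list of every observed component (component id, regions, t)."""
        pair_pos = {tuple(p): k for k, p in enumerate(np.asarray(self.edge_pairs).tolist())}
        rows = []
        for cid, comp in enumerate(self.components, start=1):
            for i, j in comp.edges:
                t = self.edge_stats[pair_pos[(i, j)]]
                ri = region_labels[i] if region_labels else i
                rj = region_labels[j] if region_labels else j
                rows.append((cid, comp.extent, comp.fwer_p, ri, rj, float(t)))
        return pd.DataFrame(
            rows, columns=["component", "extent", "fwer_p", "region_i", "region_j", "t"]
        )

    def summary(self) -> str:
        lines = [
            "Network-based statistic",
            f"  contrast: {self.contrast}   primary threshold t0 = {self.t0}",
            f"  permutations: {self.n_perm} (seed {self.seed})",
            f"  suprathreshold components: {len(self.components)}",
        ]
        for k, c in enumerate(self.components, start=1):
            lines.append(
                f"    component {k}: {len(c.nodes)} nodes, {c.extent} edges, "
                f"FWER p = {c.fwer_p:.4f}"
            )
        if not self.components:
            lines.append("    (no edge exceeded the primary threshold)")
        return "\n".join(lines)


class NetworkBasedStatistic:
    """NBS model over a subjects x edges connectivity stack.

    Parameters
    ----------
    fc_stack : array (n_subjects, n_edges)
        Vectorized upper-triangle Fisher-z connectivity.
    design : DataFrame
        Full design matrix including the ``group`` column (patient = 1) and
        nuisance covariates.
    edge_pairs : array (n_edges, 2)
        Region-index pair of each stacked edge.
    """

    def __init__(
        self,
        fc_stack: np.ndarray,
        design: pd.DataFrame | np.ndarray,
        edge_pairs: np.ndarray,
    ):
        self.fc_stack = np.asarray(fc_stack, dtype=float)
        self.design = design
        self.edge_pairs = np.asarray(edge_pairs)
        if self.edge_pairs.shape != (self.fc_stack.shape[1], 2):
            raise ValueError(
                f"edge_pairs must be (n_edges, 2) = ({self.fc_stack.shape[1]}, 2), "
                f"got {self.edge_pairs.shape}"
            )

    def fit(
        self,
        t0: float = 3.5,
        n_perm: int = 10_000,
        seed: int = 0,
        contrast: str = "patient_lt_control",
        scheme: str = "freedman-lane",
        component_stat: str = "extent",
    ) -> NBSResult:
        """Run the permutation test; see :func:`permutation_test`."""
        return permutation_test(
            self.fc_stack,
            self.design,
            self.edge_pairs,
            t0=t0,
            n_perm=n_perm,
            seed=seed,
            contrast=contrast,
            scheme=scheme,
            component_stat=component_stat,
        )


def permutation_test(
    fc_stack: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    edge_pairs: np.ndarray,
    t0: float = 3.5,
    n_perm: int = 10_000,
    seed: int = 0,
    contrast: str = "patient_lt_control",
    scheme: str = "freedman-lane",
    component_stat: str = "extent",
) -> NBSResult:
    """Component-extent permutation FWER test.

    Freedman-Lane scheme: the reduced (nuisance-only) model is fitted once,
    its residuals are row-permuted, the permuted outcome is the reduced fit
    plus permuted residuals, and the full model is refitted to obtain the
    null edge statistics.  fwer_p = (1 + #{null max >= observed}) / (1 + n_perm).
    ``component_stat='intensity'`` replaces extent with the summed
    suprathreshold exceedance (sum of t - t0 over component edges).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if scheme not in ("freedman-lane", "labels"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if component_stat not in ("extent", "intensity"):
        raise ValueError(f"unknown component statistic {component_stat!r}")
    Y = np.asarray(fc_stack, dtype=float)
    X, gi = _design_matrix(design)
    pairs = np.asarray(edge_pairs)
    sign = CONTRASTS[contrast]
    n = Y.shape[0]

    def comp_stat(stats: np.ndarray, comps: list[Component] | None = None) -> float:
        if comps is None:
            comps = suprathreshold_components(stats, pairs, t0)
        if not comps:
            return 0.0
        if component_stat == "extent":
            return float(max(c.extent for c in comps))
        pair_pos = {tuple(p): k for k, p in enumerate(pairs.tolist())}
        return float(
            max(sum(stats[pair_pos[e]] - t0 for e in c.edges) for c in comps)
        )

    obs_stats = edgewise_stats(Y, design, contrast=contrast)
    observed = suprathreshold_components(obs_stats, pairs, t0)

    xtx_inv = np.linalg.inv(X.T @ X)
    rng = rng_from(seed, 7)
    null = np.empty(n_perm)
    if scheme == "freedman-lane":
        Z = np.delete(X, gi, axis=1)
        beta_z = np.linalg.lstsq(Z, Y, rcond=None)[0]
        fitted = Z @ beta_z
        resid = Y - fitted
        for b in range(n_perm):
            perm = rng.permutation(n)
            t_b = sign * _ols_t(X, fitted + resid[perm], gi, xtx_inv=xtx_inv)
            null[b] = comp_stat(t_b)
    else:  # plain label permutation
        for b in range(n_perm):
            Xp = X.copy()
            Xp[:, gi] = X[rng.permutation(n), gi]
            t_b = sign * _ols_t(Xp, Y, gi)
            null[b] = comp_stat(t_b)

    pair_pos = {tuple(p): k for k, p in enumerate(pairs.tolist())}
    out = []
    for c in observed:
        if component_stat == "extent":
            stat_c = float(c.extent)
        else:
            stat_c = float(sum(obs_stats[pair_pos[e]] - t0 for e in c.edges))
        p = (1.0 + np.count_nonzero(null >= stat_c)) / (1.0 + n_perm)
        out.append(Component(nodes=c.nodes, edges=c.edges, fwer_p=float(p)))
    return NBSResult(
        components=out,
        null_max_extents=null,
        t0=t0,
        n_perm=n_perm,
        seed=seed,
        contrast=contrast,
        edge_stats=obs_stats,
        edge_pairs=pairs,
    )
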
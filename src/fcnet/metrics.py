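"""Binary-network graph indicators, small-world normalization, and AUC.

Global indicators: clustering coefficient Cp, characteristic path length Lp,
global efficiency E_glob, local efficiency E_loc, and the normalized pair
gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand> against an ensemble of
degree-preserving (Maslov-Sneppen rewired) random networks, with the
small-world index sigma = gamma / lambda.  Nodal indicators: degree
centrality, normalized betweenness centrality, nodal efficiency and nodal
local efficiency.  Each indicator evaluated over the density grid is
summarized by its trapezoidal area under the curve (AUC), removing the
dependence on any single threshold.

Disconnected graphs (routine at low densities): Lp averages over *reachable*
ordered pairs only, and efficiency-type metrics use 1/inf = 0.  This keeps Lp
finite everywhere on the grid; it is the convention of the common connectome
toolboxes but does change lambda relative to penalised alternatives, so it is
stated here prominently.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._utils import rng_from
from .connectome import BinaryNetwork, DensityGrid, FCMatrix, binarize_at_density

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsemble",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "double_edge_swap",
    "random_ensemble",
    "normalized_small_world",
    "metric_auc",
    "global_metrics",
    "compute_metric_curves",
    "auc_table",
]

GLOBAL_METRICS = ("cp", "lp", "gamma", "lambda", "sigma", "e_glob", "e_loc")
NODAL_METRICS = ("dc", "bc", "ne", "nle")


@dataclass(frozen=True)
class GlobalMetrics:
    cp: float
    lp: float
    gamma: float
    lambda_: float
    sigma: float
    e_glob: float
    e_loc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp,
            "lp": self.lp,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "e_glob": self.e_glob,
            "e_loc": self.e_loc,
        }


@dataclass(frozen=True)
class NodalMetrics:
    """Per-region indicator arrays (length N each)."""

    dc: np.ndarray
    bc: np.ndarray
    ne: np.ndarray
    nle: np.ndarray


@dataclass
class NullEnsemble:
    """Degree-preserving random networks for small-world normalization."""

    source_id: str
    networks: list[np.ndarray]
    seed: int

    @property
    def n_random(self) -> int:
        return len(self.networks)


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(float)
    return np.asarray(net, dtype=float)


def _distances(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def clustering_coefficient(net: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering: c_i = 2 triangles_i / (k_i (k_i - 1)),
    with c_i = 0 for degree < 2; Cp is the mean over all nodes."""
    a = _adj(net)
    n = a.shape[0]
    if n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    deg = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * triangles per node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return float(c.mean()), c


def characteristic_path_length(net: BinaryNetwork | np.ndarray) -> float:
    """Mean shortest-path length over reachable ordered pairs (hops).

    Unreachable pairs are excluded from the average; a graph with no edges
    has no reachable pair and raises."""
    a = _adj(net)
    if a.shape[0] < 2:
        raise ValueError("path length needs at least 2 nodes")
    d = _distances(a)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise ValueError("graph has no edges; characteristic path length undefined")
    return float(d[finite].mean())


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """E_glob = mean over ordered pairs of 1/d_ij, with 1/inf = 0."""
    a = _adj(net)
    n = a.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = _distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _nodal_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    nle = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        nle[i] = global_efficiency(a[np.ix_(nb, nb)])
    return nle


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbour-induced subgraph (0 for nodes with < 2 neighbours)."""
    return float(_nodal_local_efficiency(_adj(net)).mean())


def nodal_metrics(net: BinaryNetwork | np.ndarray) -> NodalMetrics:
    """Degree, normalized betweenness (Brandes, / ((N-1)(N-2)/2)), nodal
    efficiency, and nodal local efficiency per region."""
    a = _adj(net)
    n = a.shape[0]
    if n < 3:
        raise ValueError("nodal metrics need at least 3 nodes")
    dc = a.sum(axis=1)
    g = nx.from_numpy_array(a)
    bc_dict = nx.betweenness_centrality(g, normalized=True)
    bc = np.array([bc_dict[i] for i in range(n)])
    d = _distances(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(dc=dc, bc=bc, ne=ne, nle=_nodal_local_efficiency(a))


def double_edge_swap(
    adjacency: np.ndarray, n_attempts: int, rng: np.random.Generator
) -> np.ndarray:
    """Maslov-Sneppen rewiring: ``n_attempts`` attempted double-edge swaps.

    Each attempt picks two edges (u,v), (x,y), randomly orients the second,
    and replaces them with (u,x), (v,y) when that creates no self-loop or
    multi-edge.  Degree sequence is preserved exactly.
    """
    a = np.asarray(adjacency, dtype=np.int8).copy()
    iu, ju = np.nonzero(np.triu(a, 1))
    edges = np.stack([iu, ju], axis=1)
    n_edges = edges.shape[0]
    if n_edges < 2:
        return a
    picks = rng.integers(0, n_edges, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flips[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (u, x) if u < x else (x, u)
        edges[e2] = (v, y) if v < y else (y, v)
    return a


def random_ensemble(
    net: BinaryNetwork | np.ndarray,
    n_random: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Ensemble of degree-preserving rewired networks (10 x E attempted swaps
    per network by default)."""
    a = _adj(net).astype(np.int8)
    n_edges = int(a.sum() // 2)
    sid = net.subject_id if isinstance(net, BinaryNetwork) else ""
    if n_edges < 2:
        warnings.warn(
            "fewer than 2 edges: degree-preserving rewiring impossible; "
            "returning copies of the input network",
            stacklevel=2,
        )
        return NullEnsemble(source_id=sid, networks=[a.copy() for _ in range(n_random)], seed=seed)
    nets = [
        double_edge_swap(a, swaps_per_edge * n_edges, rng_from(seed, k))
        for k in range(n_random)
    ]
    return NullEnsemble(source_id=sid, networks=nets, seed=seed)


def normalized_small_world(
    net: BinaryNetwork | np.ndarray, ensemble: NullEnsemble
) -> tuple[float, float, float]:
    """gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand>, sigma = gamma/lambda,
    normalizing against the ensemble means."""
    if ensemble.n_random == 0:
        raise ValueError("empty null ensemble")
    cp, _ = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    cp_rand = np.mean([clustering_coefficient(r)[0] for r in ensemble.networks])
    lp_rand = np.mean([characteristic_path_length(r) for r in ensemble.networks])
    if cp_rand <= 0:
        raise ValueError("null-ensemble mean clustering is 0; gamma undefined")
    gamma = cp / cp_rand
    lambda_ = lp / lp_rand
    return gamma, lambda_, gamma / lambda_


def metric_auc(densities: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal integral of a metric curve over the density grid."""
    d = np.asarray(densities, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.size != v.size:
        raise ValueError(f"lengths differ: {d.size} densities vs {v.size} values")
    if d.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    return float(np.trapezoid(v, d))


def global_metrics(net: BinaryNetwork | np.ndarray, ensemble: NullEnsemble) -> GlobalMetrics:
    """All global indicators of one binary network, normalized against the
    given null ensemble."""
    cp, _ = clustering_coefficient(net)
    lp = characteristic_path_length(net)
    gamma, lambda_, sigma = normalized_small_world(net, ensemble)
    return GlobalMetrics(
        cp=cp,
        lp=lp,
        gamma=gamma,
        lambda_=lambda_,
        sigma=sigma,
        e_glob=global_efficiency(net),
        e_loc=local_efficiency(net),
    )


def compute_metric_curves(
    fcs: list[FCMatrix],
    grid: DensityGrid,
    n_random: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global and nodal indicator curves for every subject over the grid.

    Returns tidy long-format tables:
    global — columns (subject_id, density, metric, value);
    nodal  — columns (subject_id, density, region, metric, value).
    Null ensembles are seeded per (subject, density) from ``seed``.
    """
    grows: list[tuple] = []
    nrows: list[tuple] = []
    for s_idx, fc in enumerate(fcs):
        labels = fc.region_labels
        for d_idx, d in enumerate(grid.values):
            net = binarize_at_density(fc, float(d))
            ens = random_ensemble(
                net, n_random=n_random, seed=rng_from(seed, s_idx, d_idx).integers(2**31),
                swaps_per_edge=swaps_per_edge,
            )
            gm = global_metrics(net, ens)
            grows += [(fc.subject_id, float(d), k, v) for k, v in gm.as_dict().items()]
            nm = nodal_metrics(net)
            for m in NODAL_METRICS:
                vals = getattr(nm, m)
                nrows += [
                    (fc.subject_id, float(d), labels[r], m, float(vals[r]))
                    for r in range(len(labels))
                ]
    gdf = pd.DataFrame(grows, columns=["subject_id", "density", "metric", "value"])
    ndf = pd.DataFrame(nrows, columns=["subject_id", "density", "region", "metric", "value"])
    return gdf, ndf


def auc_table(curves: pd.DataFrame, densities: np.ndarray) -> pd.DataFrame:
    """AUC per subject x metric (x region for nodal tables) over the given
    densities, in wide format (one row per subject [x region])."""
    sel = curves[np.isin(np.round(curves["density"], 10), np.round(densities, 10))]
    keys = ["subject_id"] + (["region"] if "region" in curves.columns else [])
    out = (
        sel.sort_values(keys + ["metric", "density"])
        .groupby(keys + ["metric"], sort=True)
        .apply(
            lambda g: metric_auc(g["density"].to_numpy(), g["value"].to_numpy()),
            include_groups=False,
        )
        .unstack("metric")
        .reset_index()
    )
    out.columns.name = None
    return out
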